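# Phosphonate and phosphinate metabolism (KEGG map00440) EC panel, snapshot 2024-06; 31 EC numbers.
# phnGHIL is EC 2.7.8.37 (alpha-D-ribose 1-methylphosphonate 5-triphosphate synthase).
# Process labels follow the figure-level grouping; membership is editable.
gene	ec	process
phnJ	4.7.1.1	phosphonate degradation C-P lyase
phnGHIL	2.7.8.37	phosphonate degradation C-P lyase
phnM	3.6.1.63	phosphonate degradation C-P lyase
phnN	2.7.4.23	phosphonate degradation C-P lyase
phnO	2.3.1.280	phosphonate degradation C-P lyase
phnP	3.1.4.55	phosphonate degradation C-P lyase
phnW	2.6.1.37	alternative phosphonate degradation
phnX	3.11.1.1	alternative phosphonate degradation
phnA	3.11.1.2	alternative phosphonate degradation
palA	3.11.1.3	alternative phosphonate degradation
palB	2.6.1.-	alternative phosphonate degradation
phnY	1.14.11.46	alternative phosphonate degradation
phnZ	1.13.11.77	alternative phosphonate degradation
pepM	5.4.2.9	bialaphos biosynthesis
ppd	4.1.1.82	bialaphos biosynthesis
phpC	1.1.1.309	bialaphos biosynthesis
phpD	1.13.11.72	bialaphos biosynthesis
phpE	1.14.11.-	bialaphos biosynthesis
phpH	4.2.1.166	bialaphos biosynthesis
phpI	1.2.1.-	bialaphos biosynthesis
phpK	2.1.1.308	bialaphos biosynthesis
pmmS	2.3.3.18	bialaphos biosynthesis
PPT	2.3.1.183	bialaphos biosynthesis
mpnS	1.13.11.73	FR 900098 biosynthesis
frbC	2.3.3.-	FR 900098 biosynthesis
frbD	3.1.3.76	FR 900098 biosynthesis
frbG	1.14.13.-	FR 900098 biosynthesis
aepCT	2.7.7.-	phospholipid biosynthesis
aepPT	2.7.8.-	phospholipid biosynthesis
pldA	3.1.4.46	phospholipid biosynthesis
psd	4.1.1.65	phospholipid biosynthesis
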
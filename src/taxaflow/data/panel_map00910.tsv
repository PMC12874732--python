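# Nitrogen metabolism (KEGG map00910) EC panel, snapshot 2024-06; 39 EC numbers.
# Composite symbols (e.g. narGZHYIV) group subunits/isofunctional genes sharing an EC.
# Process labels follow the figure-level grouping; membership is editable.
gene	ec	process
glnA	6.3.1.2	ammonium assimilation
gdhA	1.4.1.3	ammonium assimilation
gdhA2	1.4.1.4	ammonium assimilation
carAB	6.3.5.5	ammonium assimilation
cpsIII	6.3.4.16	ammonium assimilation
gltBD	1.4.1.13	glutamate metabolism
gltB2	1.4.1.14	glutamate metabolism
gltS	1.4.7.1	glutamate metabolism
gudB	1.4.1.2	ammonium release
glsA	3.5.1.2	ammonium release
ureABC	3.5.1.5	ammonium release
fmdA	3.5.1.49	ammonium release
nit	3.5.5.1	ammonium release
cynS	4.2.1.104	ammonium release
can	4.2.1.1	ammonium release
arcC	2.7.2.2	ammonium release
uca	6.3.4.6	ammonium release
atzF	3.5.1.54	ammonium release
pmoABC-amoABC	1.14.99.39	nitrification
hao	1.7.2.6	nitrification
hox	1.7.3.4	nitrification
hcp	1.7.99.1	nitrification
napAB	1.9.6.1	denitrification
nirKS	1.7.2.1	denitrification
norBC	1.7.2.5	denitrification
nosZ	1.7.2.4	denitrification
hzsABC	1.7.2.7	denitrification
hdh	1.7.2.8	denitrification
narGZHYIV	1.7.5.1	dissimilatory nitrate reduction
nirBD	1.7.1.15	dissimilatory nitrate reduction
nrfAH	1.7.2.2	dissimilatory nitrate reduction
nirA	1.7.7.1	assimilatory nitrate reduction
narB	1.7.7.2	assimilatory nitrate reduction
NR	1.7.1.1	assimilatory nitrate reduction
nasB	1.7.1.2	assimilatory nitrate reduction
nadR	1.7.1.3	assimilatory nitrate reduction
nirB2	1.7.1.4	assimilatory nitrate reduction
nifDKH	1.18.6.1	nitrogen fixation
vnfDKG	1.19.6.1	nitrogen fixation
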
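# HPS-style hydropathy-scale CG parameter table: one bead per residue.
# sigma_nm: van-der-Waals bead diameter; lambda: normalized hydropathy
# stickiness; charge: net charge at neutral pH (e); mass: residue mass (amu).
residue	sigma_nm	lambda	charge	mass
A	0.504	0.730	0.0	71.08
R	0.656	0.000	1.0	156.19
N	0.568	0.432	0.0	114.10
D	0.558	0.378	-1.0	115.09
C	0.548	0.595	0.0	103.14
Q	0.602	0.514	0.0	128.13
E	0.592	0.459	-1.0	129.12
G	0.450	0.649	0.0	57.05
H	0.608	0.514	0.5	137.14
I	0.618	0.973	0.0	113.16
L	0.618	0.973	0.0	113.16
K	0.636	0.514	1.0	128.17
M	0.618	0.838	0.0	131.19
F	0.636	1.000	0.0	147.18
P	0.556	1.000	0.0	97.12
S	0.518	0.595	0.0	87.08
T	0.562	0.676	0.0	101.10
W	0.678	0.946	0.0	186.21
Y	0.646	0.865	0.0	163.18
V	0.586	0.892	0.0	99.07
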
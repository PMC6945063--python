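# Theoretical maximum accessible surface area per residue type (A^2),
# used to normalize residue SASA to relative solvent accessibility (%).
# Values are the published theoretical maxima of Tien et al. (2013),
# PLoS ONE 8:e80635, computed on extended Gly-X-Gly tripeptides.
# SEP is an in-house approximate value (serine maximum enlarged for the
# phosphate group); it is marked approximate in the last column.
# columns: res_name	max_asa	note
ALA	129.0	theoretical
ARG	274.0	theoretical
ASN	195.0	theoretical
ASP	193.0	theoretical
CYS	167.0	theoretical
GLN	225.0	theoretical
GLU	223.0	theoretical
GLY	104.0	theoretical
HIS	224.0	theoretical
ILE	197.0	theoretical
LEU	201.0	theoretical
LYS	236.0	theoretical
MET	224.0	theoretical
PHE	240.0	theoretical
PRO	159.0	theoretical
SER	155.0	theoretical
THR	172.0	theoretical
TRP	285.0	theoretical
TYR	263.0	theoretical
VAL	174.0	theoretical
SEP	230.0	approximate
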
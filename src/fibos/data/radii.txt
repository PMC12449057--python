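# Van der Waals radii (Angstrom) used for occluded-surface packing.
# Two kinds of entries:
#   ELEMENT RADIUS          element fallback, e.g.  "C 1.70"
#   RES:ATOM RADIUS         residue/atom override, e.g.  "ALA:CB 1.70"
# Values follow the Bondi/protein-structure convention commonly used for
# packing and surface-area calculations.
C 1.70
N 1.55
O 1.52
S 1.80
H 1.20
P 1.80
SE 1.90
F 1.47
CL 1.75
BR 1.85
I 1.98
ZN 1.39
MG 1.73
FE 1.40
CA 2.00
NA 2.27
K 2.75
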
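# Rotamer library: modal chi angles (degrees) of the common sidechain
# rotamers for the 18 chi-bearing amino-acid types, in the penultimate
# style (p/t/m naming for chi ~ +60 / 180 / -60).
# Columns: residue  rotamer  chi1 [chi2 [chi3 [chi4]]]
SER p      62
SER t     178
SER m     -65
CYS p      62
CYS t    -177
CYS m     -65
THR p      62
THR t    -175
THR m     -65
VAL p      63     # chi1 only
VAL t     175
VAL m     -60
ILE pt     62   170
ILE tt   -177   166
ILE mt    -65   170
ILE mm    -57   -60
LEU tp   -177    65
LEU tt   -172   145
LEU mt    -65   175
PRO endo  -25   35
PRO exo    25  -35
ASP p-10   62   -10
ASP t0   -177     0
ASP m-20  -70   -20
ASN p-10   62   -10
ASN t-20 -174   -20
ASN m-40  -65   -40
ASN m110  -65   110
HIS p-80   62   -75
HIS t-160 -177  -165
HIS t60  -177    65
HIS m-70  -65   -70
HIS m170  -65   175
PHE p90    62    90
PHE t80  -177    80
PHE m-85  -65   -85
TYR p90    62    90
TYR t80  -177    80
TYR m-85  -65   -85
TRP p-90   62   -90
TRP t-105 -177  -105
TRP t90  -177    90
TRP m95   -65    95
TRP m-5   -65    -5
MET ttp  -177   179    75
MET mtp   -67   178    75
MET mtm   -67   178   -75
MET mmm   -65   -65   -70
GLU tt0  -177   177     0
GLU mt-10 -67   178   -10
GLU mm-40 -65   -65   -40
GLU pt-20  62   180   -20
GLN tt0  -177   177     0
GLN mt0   -67   178     0
GLN mm-40 -65   -65   -40
GLN pt20   62   180    20
LYS tttt -177   179   179   179
LYS mttt  -65   179   179   179
LYS mmtt  -65   -68   180   180
LYS ttmt -177   179   -68   180
ARG mtt180 -67  177   180   180
ARG ttt180 -177 177   180   180
ARG mtm180 -67  176   -65   175
ARG mmt180 -62  -68   180   180
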
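REMARK   idealized united-atom group geometries for DNA
REMARK   groups: BBN backbone (phosphate+deoxyribose), ADE, GUA, CYT, THY
ATOM      1  P   BBN A   1       1.979  -0.314  -2.812  1.00  0.00           P
ATOM      2  OP1 BBN A   1       2.826   0.838  -2.431  1.00  0.00           O
ATOM      3  OP2 BBN A   1       0.841   0.173  -3.841  1.00  0.00           O
ATOM      4  O5' BBN A   1       1.286  -0.929  -1.496  1.00  0.00           O
ATOM      5  C5' BBN A   1       0.496   0.112  -0.920  1.00  0.00           C
ATOM      6  C4' BBN A   1      -0.194  -0.409   0.342  1.00  0.00           C
ATOM      7  O4' BBN A   1       0.778  -0.722   1.366  1.00  0.00           O
ATOM      8  C3' BBN A   1      -1.060   0.701   0.989  1.00  0.00           C
ATOM      9  O3' BBN A   1      -2.364   0.737   0.406  1.00  0.00           O
ATOM     10  C2' BBN A   1      -1.128   0.240   2.464  1.00  0.00           C
ATOM     11  C1' BBN A   1       0.080  -0.703   2.621  1.00  0.00           C
ATOM     12 HOP2 BBN A   1       0.313  -0.605  -4.063  1.00  0.00           H
ATOM     13  H5' BBN A   1      -0.257   0.436  -1.639  1.00  0.00           H
ATOM     14 H5'' BBN A   1       1.137   0.954  -0.662  1.00  0.00           H
ATOM     15  H4' BBN A   1      -0.801  -1.284   0.112  1.00  0.00           H
ATOM     16  H3' BBN A   1      -0.572   1.672   0.906  1.00  0.00           H
ATOM     17  H2' BBN A   1      -2.058  -0.294   2.655  1.00  0.00           H
ATOM     18 H2'' BBN A   1      -1.034   1.095   3.135  1.00  0.00           H
ATOM     19  H1' BBN A   1      -0.264  -1.707   2.870  1.00  0.00           H
ATOM     20  N9  ADE A   2      -0.768  -0.149  -2.301  1.00  0.00           N
ATOM     21  C8  ADE A   2       0.272   0.715  -2.464  1.00  0.00           C
ATOM     22  N7  ADE A   2       0.845   0.942  -1.318  1.00  0.00           N
ATOM     23  C5  ADE A   2       0.207   0.244  -0.348  1.00  0.00           C
ATOM     24  C6  ADE A   2       0.379   0.094   1.038  1.00  0.00           C
ATOM     25  N6  ADE A   2       1.389   0.767   1.703  1.00  0.00           N
ATOM     26  N1  ADE A   2      -0.454  -0.705   1.697  1.00  0.00           N
ATOM     27  C2  ADE A   2      -1.419  -1.351   1.071  1.00  0.00           C
ATOM     28  N3  ADE A   2      -1.615  -1.246  -0.226  1.00  0.00           N
ATOM     29  C4  ADE A   2      -0.832  -0.470  -0.969  1.00  0.00           C
ATOM     30  H8  ADE A   2       0.576   1.148  -3.405  1.00  0.00           H
ATOM     31  H61 ADE A   2       1.495   0.659   2.661  1.00  0.00           H
ATOM     32  H62 ADE A   2       1.993   1.345   1.210  1.00  0.00           H
ATOM     33  H2  ADE A   2      -2.073  -1.991   1.645  1.00  0.00           H
ATOM     34  N9  GUA A   3       0.199   0.311   2.500  1.00  0.00           N
ATOM     35  C8  GUA A   3      -0.905   1.077   2.734  1.00  0.00           C
ATOM     36  N7  GUA A   3      -1.537   1.294   1.617  1.00  0.00           N
ATOM     37  C5  GUA A   3      -0.878   0.682   0.603  1.00  0.00           C
ATOM     38  C6  GUA A   3      -1.094   0.577  -0.791  1.00  0.00           C
ATOM     39  O6  GUA A   3      -2.054   1.114  -1.316  1.00  0.00           O
ATOM     40  N1  GUA A   3      -0.206  -0.127  -1.526  1.00  0.00           N
ATOM     41  C2  GUA A   3       0.860  -0.728  -0.928  1.00  0.00           C
ATOM     42  N2  GUA A   3       1.741  -1.443  -1.699  1.00  0.00           N
ATOM     43  N3  GUA A   3       1.071  -0.639   0.366  1.00  0.00           N
ATOM     44  C4  GUA A   3       0.240   0.048   1.158  1.00  0.00           C
ATOM     45  H8  GUA A   3      -1.210   1.448   3.702  1.00  0.00           H
ATOM     46  H1  GUA A   3      -0.334  -0.213  -2.484  1.00  0.00           H
ATOM     47  H21 GUA A   3       2.507  -1.873  -1.288  1.00  0.00           H
ATOM     48  H22 GUA A   3       1.596  -1.522  -2.655  1.00  0.00           H
ATOM     49  N1  CYT A   4      -1.132  -0.427  -1.604  1.00  0.00           N
ATOM     50  C2  CYT A   4      -0.595   0.805  -1.569  1.00  0.00           C
ATOM     51  O2  CYT A   4      -0.813   1.581  -2.485  1.00  0.00           O
ATOM     52  N3  CYT A   4       0.172   1.192  -0.551  1.00  0.00           N
ATOM     53  C4  CYT A   4       0.426   0.369   0.457  1.00  0.00           C
ATOM     54  N4  CYT A   4       1.220   0.779   1.503  1.00  0.00           N
ATOM     55  C5  CYT A   4      -0.119  -0.931   0.448  1.00  0.00           C
ATOM     56  C6  CYT A   4      -0.900  -1.308  -0.591  1.00  0.00           C
ATOM     57  H41 CYT A   4       1.596   1.673   1.504  1.00  0.00           H
ATOM     58  H42 CYT A   4       1.400   0.176   2.241  1.00  0.00           H
ATOM     59  H5  CYT A   4       0.078  -1.614   1.262  1.00  0.00           H
ATOM     60  H6  CYT A   4      -1.332  -2.297  -0.618  1.00  0.00           H
ATOM     61  N1  THY A   5       0.697   1.769   0.717  1.00  0.00           N
ATOM     62  C2  THY A   5       1.866   1.272   0.102  1.00  0.00           C
ATOM     63  O2  THY A   5       2.944   1.871   0.091  1.00  0.00           O
ATOM     64  N3  THY A   5       1.727   0.023  -0.512  1.00  0.00           N
ATOM     65  C4  THY A   5       0.581  -0.754  -0.572  1.00  0.00           C
ATOM     66  O4  THY A   5       0.528  -1.847  -1.129  1.00  0.00           O
ATOM     67  C5  THY A   5      -0.610  -0.164   0.097  1.00  0.00           C
ATOM     68  C7  THY A   5      -1.887  -0.941   0.075  1.00  0.00           C
ATOM     69  C6  THY A   5      -0.480   1.032   0.686  1.00  0.00           C
ATOM     70  H3  THY A   5       2.556  -0.355  -0.961  1.00  0.00           H
ATOM     71  H71 THY A   5      -2.202  -1.100  -0.955  1.00  0.00           H
ATOM     72  H72 THY A   5      -2.661  -0.392   0.609  1.00  0.00           H
ATOM     73  H73 THY A   5      -1.738  -1.905   0.561  1.00  0.00           H
ATOM     74  H6  THY A   5      -1.324   1.498   1.186  1.00  0.00           H
END
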
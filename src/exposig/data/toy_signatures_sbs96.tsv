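Type	background	exposure
A[C>A]A	0.00375	0.05625
A[C>A]C	0.00375	0.05625
A[C>A]G	0.00375	0.05625
A[C>A]T	0.00375	0.05625
C[C>A]A	0.00375	0.0703125
C[C>A]C	0.00375	0.0703125
C[C>A]G	0.00375	0.0703125
C[C>A]T	0.00375	0.0703125
G[C>A]A	0.00375	0.0375
G[C>A]C	0.00375	0.0375
G[C>A]G	0.00375	0.0375
G[C>A]T	0.00375	0.0375
T[C>A]A	0.00375	0.0234375
T[C>A]C	0.00375	0.0234375
T[C>A]G	0.00375	0.0234375
T[C>A]T	0.00375	0.0234375
A[C>G]A	0.00375	0.003125
A[C>G]C	0.00375	0.003125
A[C>G]G	0.00375	0.003125
A[C>G]T	0.00375	0.003125
C[C>G]A	0.00375	0.003125
C[C>G]C	0.00375	0.003125
C[C>G]G	0.00375	0.003125
C[C>G]T	0.00375	0.003125
G[C>G]A	0.00375	0.003125
G[C>G]C	0.00375	0.003125
G[C>G]G	0.00375	0.003125
G[C>G]T	0.00375	0.003125
T[C>G]A	0.00375	0.003125
T[C>G]C	0.00375	0.003125
T[C>G]G	0.00375	0.003125
T[C>G]T	0.00375	0.003125
A[C>T]A	0.02625	0.00625
A[C>T]C	0.02625	0.00625
A[C>T]G	0.02625	0.00625
A[C>T]T	0.02625	0.00625
C[C>T]A	0.02625	0.00625
C[C>T]C	0.02625	0.00625
C[C>T]G	0.02625	0.00625
C[C>T]T	0.02625	0.00625
G[C>T]A	0.02625	0.00625
G[C>T]C	0.02625	0.00625
G[C>T]G	0.02625	0.00625
G[C>T]T	0.02625	0.00625
T[C>T]A	0.02625	0.00625
T[C>T]C	0.02625	0.00625
T[C>T]G	0.02625	0.00625
T[C>T]T	0.02625	0.00625
A[T>A]A	0.003125	0.0025
A[T>A]C	0.003125	0.0025
A[T>A]G	0.003125	0.0025
A[T>A]T	0.003125	0.0025
C[T>A]A	0.003125	0.0025
C[T>A]C	0.003125	0.0025
C[T>A]G	0.003125	0.0025
C[T>A]T	0.003125	0.0025
G[T>A]A	0.003125	0.0025
G[T>A]C	0.003125	0.0025
G[T>A]G	0.003125	0.0025
G[T>A]T	0.003125	0.0025
T[T>A]A	0.003125	0.0025
T[T>A]C	0.003125	0.0025
T[T>A]G	0.003125	0.0025
T[T>A]T	0.003125	0.0025
A[T>C]A	0.020625	0.001875
A[T>C]C	0.020625	0.001875
A[T>C]G	0.020625	0.001875
A[T>C]T	0.020625	0.001875
C[T>C]A	0.020625	0.001875
C[T>C]C	0.020625	0.001875
C[T>C]G	0.020625	0.001875
C[T>C]T	0.020625	0.001875
G[T>C]A	0.020625	0.001875
G[T>C]C	0.020625	0.001875
G[T>C]G	0.020625	0.001875
G[T>C]T	0.020625	0.001875
T[T>C]A	0.020625	0.001875
T[T>C]C	0.020625	0.001875
T[T>C]G	0.020625	0.001875
T[T>C]T	0.020625	0.001875
A[T>G]A	0.005	0.001875
A[T>G]C	0.005	0.001875
A[T>G]G	0.005	0.001875
A[T>G]T	0.005	0.001875
C[T>G]A	0.005	0.001875
C[T>G]C	0.005	0.001875
C[T>G]G	0.005	0.001875
C[T>G]T	0.005	0.001875
G[T>G]A	0.005	0.001875
G[T>G]C	0.005	0.001875
G[T>G]G	0.005	0.001875
G[T>G]T	0.005	0.001875
T[T>G]A	0.005	0.001875
T[T>G]C	0.005	0.001875
T[T>G]G	0.005	0.001875
T[T>G]T	0.005	0.001875
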
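context	POLE_like	MMR_like	APOBEC_like	Flat
A[C>A]A	0.000607	0.000653	0.000825	0.010385
A[C>A]C	0.000607	0.000653	0.000825	0.010417
A[C>A]G	0.000607	0.000653	0.000825	0.010417
A[C>A]T	0.000607	0.000653	0.000825	0.010417
C[C>A]A	0.072816	0.000653	0.000825	0.010417
C[C>A]C	0.072816	0.000653	0.000825	0.010417
C[C>A]G	0.072816	0.000653	0.000825	0.010417
C[C>A]T	0.072816	0.000653	0.000825	0.010417
G[C>A]A	0.000607	0.000653	0.000825	0.010417
G[C>A]C	0.000607	0.000653	0.000825	0.010417
G[C>A]G	0.000607	0.000653	0.000825	0.010417
G[C>A]T	0.000607	0.000653	0.000825	0.010417
T[C>A]A	0.000607	0.000653	0.000825	0.010417
T[C>A]C	0.000607	0.000653	0.000825	0.010417
T[C>A]G	0.000607	0.000653	0.000825	0.010417
T[C>A]T	0.364057	0.000653	0.000825	0.010417
A[C>G]A	0.000607	0.000653	0.000825	0.010417
A[C>G]C	0.000607	0.000653	0.000825	0.010417
A[C>G]G	0.000607	0.000653	0.000825	0.010417
A[C>G]T	0.000607	0.000653	0.000825	0.010417
C[C>G]A	0.000607	0.000653	0.000825	0.010417
C[C>G]C	0.000607	0.000653	0.000825	0.010417
C[C>G]G	0.000607	0.000653	0.000825	0.010417
C[C>G]T	0.000607	0.000653	0.000825	0.010417
G[C>G]A	0.000607	0.000653	0.000825	0.010417
G[C>G]C	0.000607	0.000653	0.000825	0.010417
G[C>G]G	0.000607	0.000653	0.000825	0.010417
G[C>G]T	0.000607	0.000653	0.000825	0.010417
T[C>G]A	0.000607	0.000653	0.231031	0.010417
T[C>G]C	0.000607	0.000653	0.000825	0.010417
T[C>G]G	0.000607	0.000653	0.000825	0.010417
T[C>G]T	0.000607	0.000653	0.231023	0.010417
A[C>T]A	0.000607	0.000653	0.000825	0.010417
A[C>T]C	0.000607	0.000653	0.000825	0.010417
A[C>T]G	0.000607	0.156638	0.000825	0.010417
A[C>T]T	0.000607	0.000653	0.000825	0.010417
C[C>T]A	0.000607	0.000653	0.000825	0.010417
C[C>T]C	0.000607	0.000653	0.000825	0.010417
C[C>T]G	0.000607	0.156658	0.000825	0.010417
C[C>T]T	0.000607	0.000653	0.000825	0.010417
G[C>T]A	0.000607	0.000653	0.000825	0.010417
G[C>T]C	0.000607	0.000653	0.000825	0.010417
G[C>T]G	0.000607	0.156658	0.000825	0.010417
G[C>T]T	0.000607	0.000653	0.000825	0.010417
T[C>T]A	0.000607	0.000653	0.231023	0.010417
T[C>T]C	0.000607	0.000653	0.000825	0.010417
T[C>T]G	0.000607	0.156658	0.000825	0.010417
T[C>T]T	0.000607	0.000653	0.231023	0.010417
A[T>A]A	0.000607	0.000653	0.000825	0.010417
A[T>A]C	0.000607	0.000653	0.000825	0.010417
A[T>A]G	0.000607	0.000653	0.000825	0.010417
A[T>A]T	0.000607	0.000653	0.000825	0.010417
C[T>A]A	0.000607	0.000653	0.000825	0.010417
C[T>A]C	0.000607	0.000653	0.000825	0.010417
C[T>A]G	0.000607	0.000653	0.000825	0.010417
C[T>A]T	0.000607	0.000653	0.000825	0.010417
G[T>A]A	0.000607	0.000653	0.000825	0.010417
G[T>A]C	0.000607	0.000653	0.000825	0.010417
G[T>A]G	0.000607	0.000653	0.000825	0.010417
G[T>A]T	0.000607	0.000653	0.000825	0.010417
T[T>A]A	0.000607	0.000653	0.000825	0.010417
T[T>A]C	0.000607	0.000653	0.000825	0.010417
T[T>A]G	0.000607	0.000653	0.000825	0.010417
T[T>A]T	0.000607	0.000653	0.000825	0.010417
A[T>C]A	0.000607	0.020235	0.000825	0.010417
A[T>C]C	0.000607	0.020235	0.000825	0.010417
A[T>C]G	0.000607	0.020235	0.000825	0.010417
A[T>C]T	0.000607	0.020235	0.000825	0.010417
C[T>C]A	0.000607	0.020235	0.000825	0.010417
C[T>C]C	0.000607	0.020235	0.000825	0.010417
C[T>C]G	0.000607	0.020235	0.000825	0.010417
C[T>C]T	0.000607	0.020235	0.000825	0.010417
G[T>C]A	0.000607	0.020235	0.000825	0.010417
G[T>C]C	0.000607	0.020235	0.000825	0.010417
G[T>C]G	0.000607	0.020235	0.000825	0.010417
G[T>C]T	0.000607	0.020235	0.000825	0.010417
T[T>C]A	0.000607	0.020235	0.000825	0.010417
T[T>C]C	0.000607	0.020235	0.000825	0.010417
T[T>C]G	0.000607	0.020235	0.000825	0.010417
T[T>C]T	0.000607	0.020235	0.000825	0.010417
A[T>G]A	0.000607	0.000653	0.000825	0.010417
A[T>G]C	0.000607	0.000653	0.000825	0.010417
A[T>G]G	0.000607	0.000653	0.000825	0.010417
A[T>G]T	0.036408	0.000653	0.000825	0.010417
C[T>G]A	0.000607	0.000653	0.000825	0.010417
C[T>G]C	0.000607	0.000653	0.000825	0.010417
C[T>G]G	0.000607	0.000653	0.000825	0.010417
C[T>G]T	0.000607	0.000653	0.000825	0.010417
G[T>G]A	0.000607	0.000653	0.000825	0.010417
G[T>G]C	0.000607	0.000653	0.000825	0.010417
G[T>G]G	0.000607	0.000653	0.000825	0.010417
G[T>G]T	0.036408	0.000653	0.000825	0.010417
T[T>G]A	0.000607	0.000653	0.000825	0.010417
T[T>G]C	0.000607	0.000653	0.000825	0.010417
T[T>G]G	0.000607	0.000653	0.000825	0.010417
T[T>G]T	0.218447	0.000653	0.000825	0.010417
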
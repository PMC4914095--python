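b	n	conformation	provenance	evidence	notes
A	A	unknown	no structure determined
A	C	N3	figure (graphical), transcription uncertain	natural k-turn (A.C)=N3
A	G	N3	text	SAM-I riboswitch k-turn=N3;SAM-I riboswitch k-turn with YbxF=N3;ribosomal Kt-46=N3;ribosomal Kt-78=N3;HmKt-7 in H. marismortui 50S subunit=N1	HmKt-7 in the 50S subunit is forced into N1 by tertiary contacts and L24 binding; majority call is N3
A	U	unknown	no structure determined (no Kt-7 variant obtained)
C	A	N1	text	HmKt-7 3b3n=C.A variant in SAM-I riboswitch=N1
C	C	N1	text	HmKt-7 3b3n=C.C variant in SAM-I riboswitch=N1
C	G	N3	figure (graphical), transcription uncertain	HmKt-7 3b3n=C-G variant in SAM-I riboswitch=N3	the single N3 among the six new variant cells
C	U	N1	figure (graphical), transcription uncertain	HmKt-7 3b3n=C.U variant in SAM-I riboswitch=N1
G	A	N3	figure (graphical), transcription uncertain	natural k-turn (G.A)=N3
G	C	N3	text	U4 snRNA k-turn=N3;natural k-turn (G-C) 2=N3;natural k-turn (G-C) 3=N3
G	G	N1	text	HmKt-7 3b3n=G.G variant in SAM-I riboswitch=N1	breaks the purine-3b tendency toward N3
G	U	N3	figure (graphical), transcription uncertain	natural k-turn (G.U)=N3
U	A	N1	figure (graphical), transcription uncertain	HmKt-7 3b3n=U-A variant in SAM-I riboswitch=N1
U	C	N1	figure (graphical), transcription uncertain	HmKt-7 3b3n=U.C variant in SAM-I riboswitch=N1
U	G	N1	text	cobalamin riboswitch k-turn=N1;T. thermophilus ribosomal Kt-7=N1;ScL30e complex k-turn=N1	same conformation in three different environments
U	U	N3	text	natural k-turn (U.U) 1=N3;natural k-turn (U.U) 2=N3;natural k-turn (U.U) 3=N3
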
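# Default RepHel motif patterns.
#
# Columns (tab-separated): name, degenerate amino-acid pattern, min_score.
# Pattern syntax: one token per position; [XY] lists the allowed residues
# at that position; a lone residue allows only itself; 'x' allows any.
# A sliding window matches when at least min_score positions agree.
#
# These defaults are editable approximations written from the canonical
# motif grammar of rolling-circle replication initiators (Rep: the HUH
# metal-binding motif and the catalytic-tyrosine motif) and of SF1/PIF1
# family helicases (Walker A/B and their companion motifs). Replace them
# with a project-specific consensus when one is available.
rep1	[FY]T[LIV]NN[LIVM][LIVM][SAT]	7
rep2	[HN][LIVMA]H[AV][LIVMF][LIVMF][LIVM]G	7
rep3	Y[LIVM]Q[KR]Y[LIVM]x[KR]K	8
helI	G[SAT][PAG]G[TS]GK[ST]	7
helIa	[LIVM][CA][STA][TN][GN][LIVM][SA][QE]	7
helII	[LIVMF][LIVMF][LIVM]DE[AIV][GS][QML]	7
helIII	[GS]D[FPW][FYL]Q[LI]PP[VI]	8
helV	[VAI][LMF][ST]R[NS]Q[KR][DE]	7
helVI	Q[GN][LIVM]T[LIVM]H[KR][SA]Q	8
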
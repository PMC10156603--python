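# Placeholder residue-level bridge contact points, fixture scale.
# The residue assignments of the named human intersubunit bridges follow a
# published assignment scheme tied to a specific deposited numbering; users
# analysing deposited models must supply their own TSV with that scheme.
# Columns: bridge, chain_a (SSU side), resid_a, chain_b (LSU side), resid_b.
bridge	chain_a	resid_a	chain_b	resid_b
B2b	S	101	L	201
B2b	S	102	L	202
B2e	S	111	L	211
B7a	S	121	L	221
B8	S	131	L	231
B8	S	132	L	232
B8	S	133	L	233
B8	S	134	L	234
eB8	S	141	L	241
eB13	S	151	L	251
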
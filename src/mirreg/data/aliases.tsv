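raw_name	canonical_id
hsa-miR-9	hsa-miR-9-5p
hsa-miR-9*	hsa-miR-9-3p
hsa-mir-9-2	hsa-mir-9-2
MIR9-2	hsa-mir-9-2
MIR9-3	hsa-mir-9-3
hsa-miR-183	hsa-miR-183-5p
MIR183	hsa-mir-183
hsa-miR-182	hsa-miR-182-5p
MIR182	hsa-mir-182
hsa-miR-371	hsa-miR-371a-3p
hsa-miR-371a	hsa-miR-371a-3p
MIR371	hsa-mir-371a
hsa-miR-372	hsa-miR-372-3p
hsa-miR-373	hsa-miR-373-3p
MIR373	hsa-mir-373
hsa-miR-512-5p	hsa-miR-512-5p
MIR512-1	hsa-mir-512-1
MIR512-2	hsa-mir-512-2
MIR515-1	hsa-mir-515-1
hsa-miR-515	hsa-miR-515-5p
MIR520e	hsa-mir-520e
hsa-miR-520e	hsa-miR-520e-3p
MIR887	hsa-mir-887
hsa-miR-887	hsa-miR-887-3p
MIR216b	hsa-mir-216b
hsa-miR-216b	hsa-miR-216b-5p
hsa-miR-96	hsa-miR-96-5p
MIR96	hsa-mir-96
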
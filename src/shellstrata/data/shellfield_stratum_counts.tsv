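stratum	gene_count	orthogroup_count	gene_count_printed
Metazoa	68	61	1
Protostomia	8	6	1
Lophotrochozoa	4	4	1
Conchifera	6	6	0
Bivalvia_Gastropoda	2	2	1
Bivalvia	9	9	1
SCATTERED	174	174	0
LINEAGE_SPECIFIC	86	0	1
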
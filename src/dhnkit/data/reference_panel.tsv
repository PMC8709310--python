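gene_id	family	genome_id	genome_group	gene_set
Bradi5g10860	Bdhn1	Bd21	D-type	brachypodium
Bradi3g51200	Bdhn2	Bd21	D-type	brachypodium
Bradi1g37410	Bdhn3	Bd21	D-type	brachypodium
Bradi4g22280	Bdhn4	Bd21	D-type	brachypodium
Bradi4g22290	Bdhn5	Bd21	D-type	brachypodium
Bradi4g19525	Bdhn6	Bd21	D-type	brachypodium
Bradi3g43870	Bdhn7	Bd21	D-type	brachypodium
Bradi3g43855	Bdhn8	Bd21	D-type	brachypodium
Bradi2g47575	Bdhn9	Bd21	D-type	brachypodium
Bradi1g13330	Bdhn10	Bd21	D-type	brachypodium
Brast09G089800	Bdhn1	ABR114	S-type	brachypodium
Brast04G110500	Bdhn2	ABR114	S-type	brachypodium
Brast07G152200	Bdhn3	ABR114	S-type	brachypodium
Brast05G049400	Bdhn5	ABR114	S-type	brachypodium
Brast05G075400	Bdhn6	ABR114	S-type	brachypodium
Brast04G194300	Bdhn7	ABR114	S-type	brachypodium
Brast04G197200	Bdhn8	ABR114	S-type	brachypodium
Brast01G171900	Bdhn9	ABR114	S-type	brachypodium
Brast02G251900	Bdhn10	ABR114	S-type	brachypodium
Brahy.D05G0138300	Bdhn1	ABR113-D	D-type	brachypodium
Brahy.D03G0707100	Bdhn2	ABR113-D	D-type	brachypodium
Brahy.D01G0507100	Bdhn3	ABR113-D	D-type	brachypodium
Brahy.D04G0319400	Bdhn5	ABR113-D	D-type	brachypodium
Brahy.D04G0277700	Bdhn6	ABR113-D	D-type	brachypodium
Brahy.D03G0604200	Bdhn7	ABR113-D	D-type	brachypodium
Brahy.D03G0604000	Bdhn8	ABR113-D	D-type	brachypodium
Brahy.D02G0637300	Bdhn9	ABR113-D	D-type	brachypodium
Brahy.D01G017200	Bdhn10	ABR113-D	D-type	brachypodium
Brahy.S09G0091400	Bdhn1	ABR113-S	S-type	brachypodium
Brahy.S04G0117200	Bdhn2	ABR113-S	S-type	brachypodium
Brahy.S07G0169500	Bdhn3	ABR113-S	S-type	brachypodium
Brahy.S05G0054400	Bdhn5	ABR113-S	S-type	brachypodium
Brahy.S05G0083200	Bdhn6	ABR113-S	S-type	brachypodium
Brahy.S04G0208500	Bdhn7	ABR113-S	S-type	brachypodium
Brahy.S04G0208900	Bdhn8	ABR113-S	S-type	brachypodium
Brahy.S01G0182800	Bdhn9	ABR113-S	S-type	brachypodium
Brahy.S02G0268100	Bdhn10	ABR113-S	S-type	brachypodium
Brasy9G143400	Bdhn1	Ain-1	S-type	brachypodium
Brasy9G149400	Bdhn1	Ain-1	S-type	brachypodium
Brasy4G117200	Bdhn2	Ain-1	S-type	brachypodium
Brasy7G144000	Bdhn3	Ain-1	S-type	brachypodium
Brasy5G271500	Bdhn5	Ain-1	S-type	brachypodium
Brasy4G237500	Bdhn6	Ain-1	S-type	brachypodium
Brasy4G220100	Bdhn7	Ain-1	S-type	brachypodium
Brasy4G219800	Bdhn8	Ain-1	S-type	brachypodium
Brasy1G228900	Bdhn9	Ain-1	S-type	brachypodium
Brasy2G277500	Bdhn10	Ain-1	S-type	brachypodium
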
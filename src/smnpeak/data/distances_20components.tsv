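subject	EO_left	EO_right	EC_left	EC_right
Sub001	4	9	45	3
Sub002	31	45	14	0
Sub003	30	24	3	5
Sub004	63	59	86	3
Sub005	10	23	52	0
Sub006	3	7	24	35
Sub007	12	85	4	25
Sub008	16	58	28	60
Sub009	52	59	26	25
Sub011	38	45	69	4
Sub012	18	4	0	11
Sub013	7	68	30	3
Sub014	87	52	38	7
Sub015	0	74	0	0
Sub016	59	0	59	54
Sub017	57	81	3	22
Sub018	5	0	22	72
Sub019	38	77	23	0
Sub020	26	103	3	28
Sub021	71	67	22	20
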
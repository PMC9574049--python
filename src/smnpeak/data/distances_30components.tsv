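subject	EO_left	EO_right	EC_left	EC_right
Sub001	4	16	45	0
Sub002	42	54	0	0
Sub003	0	22	3	7
Sub004	28	3	25	4
Sub005	45	46	52	26
Sub006	77	31	24	3
Sub007	5	69	42	10
Sub008	7	0	64	77
Sub009	33	14	3	31
Sub011	0	23	-	-
Sub012	14	7	4	11
Sub013	38	43	30	7
Sub014	47	42	54	35
Sub015	55	21	28	0
Sub016	22	3	23	85
Sub017	59	64	22	18
Sub018	5	0	34	57
Sub019	35	20	21	0
Sub020	83	82	5	0
Sub021	71	61	54	40
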
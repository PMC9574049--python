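subject	EO_left	EO_right	EC_left	EC_right
Sub001	4	16	3	7
Sub002	27	0	41	0
Sub003	0	12	3	12
Sub004	14	0	4	24
Sub005	52	0	3	0
Sub006	32	23	17	13
Sub007	7	79	35	31
Sub008	3	24	4	55
Sub009	20	0	39	3
Sub011	58	33	42	47
Sub012	0	7	78	4
Sub013	19	27	36	51
Sub014	62	25	4	16
Sub015	30	21	7	26
Sub016	0	62	18	0
Sub017	19	4	4	40
Sub018	31	15	21	18
Sub019	24	19	7	26
Sub020	24	0	21	3
Sub021	3	25	5	0
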
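sample_id	total_mapped_reads	oste	ry	rx	prot
ST-30	0	Indet	Indet	Indet	M
ST-38	0	Indet	Indet	Indet	M
RTKT-5	202	M*	Indet	Indet	M
RTKT-21	384	Indet	Indet	F*	F
RTKT-4	602	M*	Indet	Indet	M
RTKT-3	614	M*	Indet	F*	M
RTKT-14	884	Indet	Indet	F*	F
RTKT-22	1499	M*	Indet	M*	M
RTKT-7C	2036	Indet	F*	M*	F
RTKT-8	2249	Indet	Indet	M*	M
ST-21	3838	Indet	F*	F*	M
ST-55	3940	Indet	F*	F*	F
ST-8	5256	Indet	M*	M	M
ST-5A	6605	Indet	F	F*	M
ST-49B	8171	M	M*	M	M
ST-31	8491	F*	F*	F*	F
ST-29	12880	F*	M*	M*	F
RTKT-12	16208	Indet	M*	M	M
ST-13	17650	M	M*	M	M
ST-35	19768	M	F*	F*	M
ST-58B	23515	Indet	F*	F*	F
ST-23	24618	Indet	F	F*	F
RTKT-19	33738	Indet	M*	M	M
ST-36	35058	F	M*	M*	F
ST-40	41720	M	Indet	Indet	M
ST-46	42606	M	Indet	M*	M
RTKT-23	42930	F*	F	F*	M
ST-51	45661	M	M	M	M
ST-27A	47008	F	F	F*	F
ST-47	56495	M	F*	F*	M
ST-10	66934	M	M	M	M
ST-5B	75045	Indet	Indet	M	M
ST-57A	88870	F	F	F*	F
RTKT-20	95017	Indet	F	F	F
ST-15	131763	Indet	M*	M	M
ST-44	136755	M	M	M	M
ST-26	140759	Indet	M*	M	M
ST-58A	174112	F*	F	F*	F
RTKT-7A	186704	F*	F	F*	F
ST-7	218316	Indet	M	M	M
RTKT-16	298184	Indet	F	F*	F
ST-32	311636	Indet	M	M	M
ST-12	577053	M*	M	M	M
ST-42	638050	Indet	M	M	M
ST-9	737923	Indet	M	M	M
RTKT-10	820699	F*	F	F	F
RTKT-17	964774	Indet	M	M	M
ST-52	1052930	M*	M	M	M
ST-56	1404346	M*	M	M	M
ST-6	1581177	F	F	F	F
ST-62	6376553	Indet	F	F	F
ST-63	10796470	Indet	M	M	M
ST-53	22121564	F	F	F	F
ST-54	24679707	Indet	F	F	F
ST-48	39132506	F	F	F*	F
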
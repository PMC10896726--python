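GLYCOLYSIS	core glycolytic enzymes	g000	g001	g002	g003	g004	g005	g006	g007
TCA_CYCLE	tricarboxylic-acid-cycle enzymes	g010	g011	g012	g013	g014	g015
SASP_CYTOKINES	inflammatory secretory programme	g020	g021	g022	g023	g024	g025	g026	g027	g028	g029
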
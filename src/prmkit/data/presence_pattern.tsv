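protein	peptide	healthy	inflamed
S100A9	DLYNFLK	-	+
LL-37	LLGDFFR	-	+
LCN2	TFVPGCQPGEFTLGNIK	-	+
S100A8	ALNSIIDVYHK	+	+
S100A8	GADVWFK	+	+
LCN2	VPLQQNFQDNQFQGK	+	+
DCD	ENAGEDPGLAR	+	+
LACRT	SILLTEQALAK	+	+
LYZ	WESGYNTR	+	+
S100A7	SIIGMIDMFHK	-	-
hBD1	IQGTCYR	-	-
hBD2	GIGDPVTCLK	-	-
hBD3	GIINTLQK	-	-
hBD4	ICGYGTAR	-	-
LCN2	SYNVTSVLFR	-	-
TSLP	CLEQVSQLQGLWR	-	-
LACRT	QELNPLK	-	-
LYZ	GISLANWMCLAK	-	-
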
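# Signed Boolean regulatory network (macpol edge-list format v1)
node	IFNg	input	M1
node	IL10	input	M2
node	IL4	input	M2
node	LPS	input	M1
node	IFNgR	receptor	M1
node	IL10R	receptor	M2
node	IL4Ra	receptor	M2
node	TLR4	receptor	M1
node	STAT1	internal	M1
node	SOCS3	internal	M1
node	NOS2	internal	M1
node	STAT6	internal	M2
node	PPARg	internal	M2
node	SOCS1	internal	M2
node	KLF4	internal	M2
node	Arg1	internal	M2
node	STAT3	internal	M2
node	NF-kB	internal	M1
marker	M1	NOS2
marker	M2	Arg1
IFNg	+	IFNgR
IL10	+	IL10R
IL4	+	IL4Ra
LPS	+	TLR4
IFNgR	+	STAT1
IL10R	+	STAT3
IL4Ra	+	STAT6
TLR4	+	NF-kB
STAT1	+	SOCS3
STAT1	+	NOS2
SOCS3	-	STAT3
STAT6	+	PPARg
STAT6	+	SOCS1
STAT6	+	KLF4
STAT6	+	Arg1
PPARg	-	NF-kB
SOCS1	-	STAT1
KLF4	-	NF-kB
STAT3	+	IL4Ra
STAT3	-	NF-kB
NF-kB	+	NOS2
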
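#tax_id	GeneID	GO_ID	Evidence	Qualifier	GO_term	PubMed	Category
9606	1	GO:0000010	IMP	-	-	1001	Process
9606	1	GO:0000011	IEA	-	-	1002	Process
9606	2	GO:0000012	IEA	-	-	1003	Process
9606	3	GO:0000020	IEA	-	-	1004	Process
9606	4	GO:0000021	ISS	-	-	1005	Process
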
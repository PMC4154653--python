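species	replicon	orf_index	strand	subunit_label
dictyoglomi	chr	0	+	I
dictyoglomi	chr	1	+	sI
dictyoglomi	chr	2	+	0A
dictyoglomi	chr	3	+	0C
dictyoglomi	chr	4	+	0B
dictyoglomi	chr	5	+	IA
dictyoglomi	chr	6	+	IG
dictyoglomi	chr	7	+	IB
dictyoglomi	chr	8	+	IE
planctomycetes	chr	0	+	I
planctomycetes	chr	1	+	sI
planctomycetes	chr	2	+	0A
planctomycetes	chr	3	+	0C
planctomycetes	chr	4	+	0B
planctomycetes	chr	5	+	ID
planctomycetes	chr	6	+	IA
planctomycetes	chr	7	+	IG
planctomycetes	chr	8	+	IB
planctomycetes	chr	9	+	IE
firmicutes	chr	0	+	I
firmicutes	chr	1	+	0A
firmicutes	chr	2	+	0C
firmicutes	chr	3	+	0B
firmicutes	chr	4	+	ID
firmicutes	chr	5	+	IA
firmicutes	chr	6	+	IG
firmicutes	chr	7	+	IB
firmicutes	chr	8	+	IE
thermotogae	chr	0	+	I
thermotogae	chr	1	+	sI
thermotogae	chr	2	+	0A
thermotogae	chr	3	+	0C
thermotogae	chr	4	+	0B
thermotogae	chr	5	+	ID
thermotogae	chr	6	+	IA
thermotogae	chr	7	+	IG
thermotogae	chr	8	+	IB
thermotogae	chr	9	+	IE
chloroflexi	chr	0	+	0A
chloroflexi	chr	1	+	0C
chloroflexi	chr	2	+	0B
chloroflexi	chr	3	+	ID
chloroflexi	chr	4	+	IA
chloroflexi	chr	5	+	IG
chloroflexi	chr	6	+	IB
chloroflexi	chr	7	+	IE
actinobacteria	chr	0	+	I
actinobacteria	chr	1	+	sI
actinobacteria	chr	2	+	0A
actinobacteria	chr	3	+	0C
actinobacteria	chr	4	+	0B
actinobacteria	chr	5	+	ID
actinobacteria	chr	6	+	IA
actinobacteria	chr	7	+	IG
actinobacteria	chr	8	+	IB
actinobacteria	chr	9	+	IE
tenericutes	chr	0	+	I
tenericutes	chr	1	+	0A
tenericutes	chr	2	+	0C
tenericutes	chr	3	+	0B
tenericutes	chr	4	+	ID
tenericutes	chr	5	+	IA
tenericutes	chr	6	+	IG
tenericutes	chr	7	+	IB
tenericutes	chr	8	+	IE
verrucomicrobia	chr	0	+	0A
verrucomicrobia	chr	1	+	0C
verrucomicrobia	chr	2	+	0B
verrucomicrobia	chr	3	+	ID
verrucomicrobia	chr	4	+	IA
verrucomicrobia	chr	5	+	IG
verrucomicrobia	chr	6	+	IB
verrucomicrobia	chr	7	+	IE
fusobacteria	chr	0	+	sI
fusobacteria	chr	1	+	0A
fusobacteria	chr	2	+	0C
fusobacteria	chr	3	+	0B
fusobacteria	chr	4	+	ID
fusobacteria	chr	5	+	IA
fusobacteria	chr	6	+	IG
fusobacteria	chr	7	+	IB
fusobacteria	chr	8	+	IE
proteobacteria_beta	chr	0	+	I
proteobacteria_beta	chr	1	+	sI
proteobacteria_beta	chr	2	+	0A
proteobacteria_beta	chr	3	+	0C
proteobacteria_beta	chr	4	+	0B
proteobacteria_beta	chr	5	+	ID
proteobacteria_beta	chr	6	+	IA
proteobacteria_beta	chr	7	+	IG
proteobacteria_beta	chr	8	+	IB
proteobacteria_beta	chr	9	+	IE
proteobacteria_gamma	chr	0	+	I
proteobacteria_gamma	chr	1	+	sI
proteobacteria_gamma	chr	2	+	0A
proteobacteria_gamma	chr	3	+	0C
proteobacteria_gamma	chr	4	+	0B
proteobacteria_gamma	chr	5	+	ID
proteobacteria_gamma	chr	6	+	IA
proteobacteria_gamma	chr	7	+	IG
proteobacteria_gamma	chr	8	+	IB
proteobacteria_gamma	chr	9	+	IE
spirochaetes	chr	0	+	I
spirochaetes	chr	1	+	sI
spirochaetes	chr	2	+	0A
spirochaetes	chr	3	+	0C
spirochaetes	chr	4	+	0B
spirochaetes	chr	5	+	ID
spirochaetes	chr	6	+	IA
spirochaetes	chr	7	+	IG
spirochaetes	chr	8	+	IB
spirochaetes	chr	9	+	IE
chlorobi	chr	0	+	I
chlorobi	chr	1	+	sI
chlorobi	chr	2	+	0A
chlorobi	chr	3	+	0C
chlorobi	chr	4	+	0B
chlorobi	chr	5	+	ID
chlorobi	chr	1005	+	IA
chlorobi	chr	1006	+	IG
chlorobi	chr	2006	+	IB
chlorobi	chr	2007	+	IE
bacteroidetes	chr	0	+	I
bacteroidetes	chr	1	+	sI
bacteroidetes	chr	2	+	0A
bacteroidetes	chr	3	+	0C
bacteroidetes	chr	4	+	0B
bacteroidetes	chr	5	+	ID
bacteroidetes	chr	6	+	IA
bacteroidetes	chr	7	+	IG
bacteroidetes	chr	1007	+	IB
bacteroidetes	chr	1008	+	IE
cyanobacteria	chr	0	+	I
cyanobacteria	chr	1	+	sI
cyanobacteria	chr	2	+	0A
cyanobacteria	chr	3	+	0C
cyanobacteria	chr	4	+	0B
cyanobacteria	chr	5	+	0B
cyanobacteria	chr	6	+	ID
cyanobacteria	chr	7	+	IA
cyanobacteria	chr	8	+	IG
cyanobacteria	chr	1008	+	IB
cyanobacteria	chr	1009	+	IE
aquificae	chr	0	+	I
aquificae	chr	1000	+	0A
aquificae	chr	1001	+	0C
aquificae	chr	2001	+	0B
aquificae	chr	2002	+	0B
aquificae	chr	2003	+	ID
aquificae	chr	2004	+	IA
aquificae	chr	3004	+	IG
aquificae	chr	4004	+	IB
aquificae	chr	5004	+	IE
nitrospirae	chr	0	+	I
nitrospirae	chr	1	+	sI
nitrospirae	chr	2	+	0A
nitrospirae	chr	3	+	0C
nitrospirae	chr	4	+	0B
nitrospirae	chr	1004	+	ID
nitrospirae	chr	1005	+	IA
nitrospirae	chr	1006	+	IG
nitrospirae	chr	1007	+	IB
nitrospirae	chr	1008	+	IE
proteobacteria_alpha	chr	0	+	I
proteobacteria_alpha	chr	1	+	sI
proteobacteria_alpha	chr	2	+	0A
proteobacteria_alpha	chr	3	+	0C
proteobacteria_alpha	chr	4	+	0B
proteobacteria_alpha	chr	5	+	0B
proteobacteria_alpha	chr	1005	+	ID
proteobacteria_alpha	chr	1006	+	IA
proteobacteria_alpha	chr	1007	+	IG
proteobacteria_alpha	chr	1008	+	IB
proteobacteria_alpha	chr	1009	+	IE
acidobacteria	chr	0	+	I
acidobacteria	chr	1	+	sI
acidobacteria	chr	2	+	0A
acidobacteria	chr	3	+	0C
acidobacteria	chr	1003	+	0B
acidobacteria	chr	1004	+	0B
acidobacteria	chr	1005	+	ID
acidobacteria	chr	1006	+	IA
acidobacteria	chr	1007	+	IG
acidobacteria	chr	1008	+	IB
acidobacteria	chr	1009	+	IE
deferribacteres	chr	0	+	I
deferribacteres	chr	1	+	sI
deferribacteres	chr	2	+	0A
deferribacteres	chr	3	+	0C
deferribacteres	chr	1003	+	0B
deferribacteres	chr	1004	+	0B
deferribacteres	chr	1005	+	ID
deferribacteres	chr	1006	+	IA
deferribacteres	chr	1007	+	IG
deferribacteres	chr	1008	+	IB
deferribacteres	chr	1009	+	IE
proteobacteria_delta	chr	0	+	I
proteobacteria_delta	chr	1	+	sI
proteobacteria_delta	chr	2	+	0A
proteobacteria_delta	chr	3	+	0C
proteobacteria_delta	chr	1003	+	0B
proteobacteria_delta	chr	1004	+	0B
proteobacteria_delta	chr	1005	+	ID
proteobacteria_delta	chr	1006	+	IA
proteobacteria_delta	chr	1007	+	IG
proteobacteria_delta	chr	1008	+	IB
proteobacteria_delta	chr	1009	+	IE
proteobacteria_epsilon	chr	0	+	I
proteobacteria_epsilon	chr	1	+	sI
proteobacteria_epsilon	chr	2	+	0A
proteobacteria_epsilon	chr	1002	+	0C
proteobacteria_epsilon	chr	2002	+	0B
proteobacteria_epsilon	chr	2003	+	0B
proteobacteria_epsilon	chr	2004	+	ID
proteobacteria_epsilon	chr	2005	+	IA
proteobacteria_epsilon	chr	2006	+	IG
proteobacteria_epsilon	chr	2007	+	IB
proteobacteria_epsilon	chr	2008	+	IE
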
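species	character	holotype	lo	hi
G. adriatica	Standard length (SL) in mm	41.41	22.95	41.03
G. adriatica	Body depth at anus	15.3	12.9	16.2
G. adriatica	Body depth at pectoral fins	15.7	11.2	14.8
G. adriatica	Body width at anus	12.1	9.8	13.0
G. adriatica	Body width at pectoral fins	16.8	13.7	16.6
G. adriatica	Caudal base depth	12.6	10.1	13.5
G. adriatica	Caudal fin length	16.3	13.9	16.4
G. adriatica	Disc length	20.1	15.9	19.0
G. adriatica	Disc width	22.3	16.3	19.0
G. adriatica	Distance between the posterior margin of sucking disc and anus	25.1	22.7	26.1
G. adriatica	Head depth at anterior sucking disc edge	14.1	11.1	14.3
G. adriatica	Head depth at orbit	12.0	8.8	12.2
G. adriatica	Head length	30.0	26.2	29.4
G. adriatica	Head width at head invagination	19.4	15.6	20.4
G. adriatica	Head width at orbit	20.1	15.8	19.6
G. adriatica	Head width at sucking disc anterior edge	20.6	17.7	23.7
G. adriatica	Horizontal eye diameter	3.2	3.0	3.7
G. adriatica	Interorbital distance	9.2	6.1	9.3
G. adriatica	Pectoral fin length	10.7	8.7	11.3
G. adriatica	Postanus length	41.3	38.1	42.2
G. adriatica	Postorbital distance	18.5	15.1	18.3
G. adriatica	Preanus length	62.3	57.7	63.5
G. adriatica	Predisc length	18.6	17.1	19.7
G. adriatica	Preorbital distance	9.4	7.5	9.7
G. adriatica	Prepectoral-fin length	28.2	25.1	28.5
G. adriatica	Vertical eye diameter	4.3	3.4	4.1
G. orientalis	Standard length (SL) in mm	32.8	17.09	37.53
G. orientalis	Body depth at anus	14.0	12.7	15.2
G. orientalis	Body depth at pectoral fins	13.0	11.6	14.4
G. orientalis	Body width at anus	11.4	10.8	12.8
G. orientalis	Body width at pectoral fins	14.5	14.2	15.7
G. orientalis	Caudal base depth	13.0	11.4	14.1
G. orientalis	Caudal fin length	15.0	14.2	17.5
G. orientalis	Disc length	17.3	14.9	19.0
G. orientalis	Disc width	18.5	16.0	18.2
G. orientalis	Distance between the posterior margin of sucking disc and anus	21.9	20.2	24.2
G. orientalis	Head depth at anterior sucking disc edge	13.5	12.1	14.9
G. orientalis	Head depth at orbit	10.0	9.4	10.8
G. orientalis	Head length	28.8	25.0	28.9
G. orientalis	Head width at head invagination	17.3	15.0	17.8
G. orientalis	Head width at orbit	18.9	15.8	18.4
G. orientalis	Head width at sucking disc anterior edge	20.4	18.3	21.3
G. orientalis	Horizontal eye diameter	2.9	2.8	4.2
G. orientalis	Interorbital distance	8.0	5.9	8.7
G. orientalis	Pectoral fin length	9.0	8.2	10.3
G. orientalis	Postanus length	43.5	35.5	43.9
G. orientalis	Postorbital distance	17.5	15.2	18.1
G. orientalis	Preanus length	60.1	55.9	60.8
G. orientalis	Predisc length	19.8	15.9	19.4
G. orientalis	Preorbital distance	9.0	7.2	9.1
G. orientalis	Prepectoral-fin length	27.8	24.7	28.2
G. orientalis	Vertical eye diameter	3.0	2.5	4.3
G. hofrichteri	Standard length (SL) in mm	30.35	20.62	36.91
G. hofrichteri	Body depth at anus	11.0	9.1	11.7
G. hofrichteri	Body depth at pectoral fins	10.1	9.5	10.9
G. hofrichteri	Body width at anus	8.6	7.4	9.1
G. hofrichteri	Body width at pectoral fins	12.3	10.3	12.4
G. hofrichteri	Caudal base depth	9.2	8.2	10.4
G. hofrichteri	Caudal fin length	12.1	11.5	13.0
G. hofrichteri	Disc length	12.1	10.2	13.4
G. hofrichteri	Disc width	15.0	12.4	16.1
G. hofrichteri	Distance between the posterior margin of sucking disc and anus	28.0	26.0	29.6
G. hofrichteri	Head depth at anterior sucking disc edge	11.4	9.9	12.2
G. hofrichteri	Head depth at orbit	8.7	7.3	9.3
G. hofrichteri	Head length	21.6	18.9	23.4
G. hofrichteri	Head width at head invagination	14.1	11.2	14.3
G. hofrichteri	Head width at orbit	14.1	11.2	14.4
G. hofrichteri	Head width at sucking disc anterior edge	16.0	14.1	17.3
G. hofrichteri	Horizontal eye diameter	2.2	2.1	2.6
G. hofrichteri	Interorbital distance	6.2	5.1	6.3
G. hofrichteri	Pectoral fin length	5.9	5.4	6.4
G. hofrichteri	Postanus length	43.4	41.8	52.6
G. hofrichteri	Postorbital distance	13.4	12.0	14.5
G. hofrichteri	Preanus length	55.5	50.8	57.1
G. hofrichteri	Predisc length	15.3	14.2	16.5
G. hofrichteri	Preorbital distance	7.2	5.7	7.8
G. hofrichteri	Prepectoral-fin length	22.1	19.5	23.7
G. hofrichteri	Vertical eye diameter	2.6	2.0	2.7
G. pigra	Standard length (SL) in mm	43.12	32.58	39.48
G. pigra	Body depth at anus	12.3	11.3	13.5
G. pigra	Body depth at pectoral fins	11.5	10.6	11.8
G. pigra	Body width at anus	9.9	8.5	11.4
G. pigra	Body width at pectoral fins	11.8	11.5	13.2
G. pigra	Caudal base depth	9.5	9.0	10.8
G. pigra	Caudal fin length	11.7	11.1	12.7
G. pigra	Disc length	13.5	12.1	14.6
G. pigra	Disc width	14.7	13.5	18.5
G. pigra	Distance between the posterior margin of sucking disc and anus	31.3	25.7	34.7
G. pigra	Head depth at anterior sucking disc edge	10.9	11.3	12.8
G. pigra	Head depth at orbit	8.5	8.0	9.8
G. pigra	Head length	19.5	20.1	22.9
G. pigra	Head width at head invagination	12.5	12.6	15.3
G. pigra	Head width at orbit	12.5	13.7	15.9
G. pigra	Head width at sucking disc anterior edge	15.6	14.2	18.4
G. pigra	Horizontal eye diameter	2.0	2.0	2.4
G. pigra	Interorbital distance	6.5	5.6	7.3
G. pigra	Pectoral fin length	5.8	5.6	7.5
G. pigra	Postanus length	42.5	42.4	46.6
G. pigra	Postorbital distance	14.0	12.6	15.2
G. pigra	Preanus length	56.1	52.8	59.4
G. pigra	Predisc length	15.1	13.2	16.5
G. pigra	Preorbital distance	7.1	5.5	8.0
G. pigra	Prepectoral-fin length	22.2	19.5	23.4
G. pigra	Vertical eye diameter	2.9	2.3	2.9
G. willdenowi	Standard length (SL) in mm	46.11	31.13	46.11
G. willdenowi	Body depth at anus	11.3	12.5	13.8
G. willdenowi	Body depth at pectoral fins	12.2	11.4	13.4
G. willdenowi	Body width at anus	8.8	9.6	11.3
G. willdenowi	Body width at pectoral fins	12.9	13.9	15.8
G. willdenowi	Caudal base depth	11.3	11.5	13.0
G. willdenowi	Caudal fin length	14.2	13.5	15.5
G. willdenowi	Disc length	17.5	17.1	19.3
G. willdenowi	Disc width	19.9	17.4	20.2
G. willdenowi	Distance between the posterior margin of sucking disc and anus	20.8	20.2	23.7
G. willdenowi	Head depth at anterior sucking disc edge	13.3	11.3	14.0
G. willdenowi	Head depth at orbit	11.0	9.4	12.4
G. willdenowi	Head length	26.8	24.3	28.8
G. willdenowi	Head width at head invagination	17.7	16.1	19.0
G. willdenowi	Head width at orbit	17.8	16.1	19.5
G. willdenowi	Head width at sucking disc anterior edge	19.6	19.0	21.9
G. willdenowi	Horizontal eye diameter	2.5	2.3	2.9
G. willdenowi	Interorbital distance	8.8	7.1	8.6
G. willdenowi	Pectoral fin length	9.2	8.6	9.3
G. willdenowi	Postanus length	39.5	39.9	42.3
G. willdenowi	Postorbital distance	15.9	15.1	17.2
G. willdenowi	Preanus length	54.1	55.8	60.8
G. willdenowi	Predisc length	16.9	16.4	18.4
G. willdenowi	Preorbital distance	9.5	8.3	10.0
G. willdenowi	Prepectoral-fin length	26.6	24.4	28.4
G. willdenowi	Vertical eye diameter	3.3	2.6	3.1
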
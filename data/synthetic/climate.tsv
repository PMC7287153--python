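taxon	wMAT	wMAP
sp01	3.102180086	321.6173288
sp02	2.803777957	324.6491492
sp03	2.557116473	239.0133883
sp04	2.486977158	371.4300708
sp05	1.055605586	311.1993437
sp06	0.4036857715	401.3237377
sp07	1.291495187	179.8795532
sp08	1.776325741	412.2646352
sp09	2.121738571	468.163054
sp10	2.006767841	266.3031825
sp11	13.73572524	199.8064832
sp12	11.90879021	284.1026919
sp13	12.76539656	221.8075151
sp14	4.814826568	363.2304705
sp15	13.87889538	134.0959134
sp16	10.97251982	745.4906674
sp17	15.25966518	227.2958039
sp18	15.98869962	149.1966245
sp19	14.77560984	246.1007019
sp20	11.64572612	113.2138824
sp21	13.86540527	186.7941557
sp22	11.90735578	809.1896787
sp23	5.161532475	337.130498
sp24	12.3060111	15.86131772
sp25	3.471771075	242.1655082
sp26	3.254137334	20.50662635
sp27	1.972797325	159.4187078
sp28	12.67344106	-32.75355575
sp29	2.811821088	43.41178137
sp30	4.908499058	84.41509121
sp31	4.970934884	253.2722892
sp32	4.516193817	253.8213777
sp33	4.513336074	181.2414535
sp34	4.677104189	222.4454394
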
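taxon	habitat
sp01	CS
sp02	CS
sp03	CS
sp04	CS
sp05	CS
sp06	CS
sp07	CS
sp08	CS
sp09	CS
sp10	CS
sp11	WA
sp12	WA
sp13	WA
sp14	CS
sp15	WA
sp16	HF
sp17	WA
sp18	WA
sp19	WA
sp20	WA
sp21	WA
sp22	HF
sp23	CS
sp24	WA
sp25	CS
sp26	CS
sp27	CS
sp28	WA
sp29	CS
sp30	CS
sp31	CS
sp32	CS
sp33	CS
sp34	CS
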
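(((sp01:0.288897043516,((sp02:0.222665481685,sp03:0.222665481685):0.000606607713071,(sp04:0.203766240122,sp05:0.203766240122):0.0195058492763):0.0656249541181):0.311102956484,(sp06:0.512375323657,((sp07:0.285128809446,sp08:0.285128809446):0.223250142103,(sp09:0.236137703198,sp10:0.236137703198):0.272241248351):0.00399637210744):0.0876246763432):0.4,(((((sp11:0.314069360824,(sp12:0.202507009989,sp13:0.202507009989):0.111562350836):0.0303628027584,sp14:0.344432163583):0.0956441148247,(sp15:0.383957506438,sp16:0.383957506438):0.0561187719697):0.159923721592,((sp17:0.292644422026,(sp18:0.24961254864,sp19:0.24961254864):0.0430318733869):0.097451806446,((sp20:0.227379836724,sp21:0.227379836724):0.138942962887,sp22:0.366322799611):0.0237734288611):0.209903771528):0.2,((sp23:0.348922435195,(((sp24:0.249371533628,sp25:0.249371533628):0.000475104103172,(sp26:0.238738925057,sp27:0.238738925057):0.0111077126738):0.0214771921174,(((sp28:0.209080801127,sp29:0.209080801127):0.00477708238551,sp30:0.213857883513):0.0253224118394,sp31:0.239180295352):0.0321435344961):0.0775986053466):0.251077564805,(sp32:0.29967576249,(sp33:0.205795138072,sp34:0.205795138072):0.0938806244179):0.30032423751):0.2):0.2);
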
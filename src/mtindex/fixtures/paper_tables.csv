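compound_id,compound_name,target_id,structure_id,score
88,Calceolarioside C,EcR,3IXP,−214.0
88,Calceolarioside C,EcR,2R40,−207.2
90,Forsythoside A,EcR,3IXP,−202.8
90,Forsythoside A,EcR,2R40,−213.5
89,Calceolarioside E,EcR,3IXP,−184.7
89,Calceolarioside E,EcR,2R40,−212.5
92,Isoarenarioside,EcR,3IXP,−183.0
92,Isoarenarioside,EcR,2R40,−205.5
87,Verbascoside,EcR,3IXP,−197.4
87,Verbascoside,EcR,2R40,−184.1
86,Calceolarioside A,EcR,3IXP,−174.2
86,Calceolarioside A,EcR,2R40,−183.6
91,Calceolarioside B,EcR,3IXP,−162.1
91,Calceolarioside B,EcR,2R40,−176.7
93,Calceolarioside D,EcR,3IXP,−160.2
93,Calceolarioside D,EcR,2R40,−169.3
68,3-Isovaleroyl-7-malonyloxy-thyrsiflorane,EcR,3IXP,−147.2
68,3-Isovaleroyl-7-malonyloxy-thyrsiflorane,EcR,2R40,−157.1
45,"3-β-Isovaleroyl-18-hydroxy-7-α-malonyloxyent-isopimara-9(11), 15-diene",EcR,3IXP,−150.2
45,"3-β-Isovaleroyl-18-hydroxy-7-α-malonyloxyent-isopimara-9(11), 15-diene",EcR,2R40,−151.5
86,Calceolarioside A,PPO,3HHS,−161.187
110,Kaempferol-7-methyl ether,PPO,3HHS,−142.825
93,Calceolarioside D,PPO,3HHS,−142.017
109,"Gossypetin-7,8,3′-trimethyl ether",PPO,3HHS,−140.618
108,"Herbacetin-8,4′-dimethyl ether",PPO,3HHS,−138.595
88,Calceolarioside C,PPO,3HHS,−137.969
111,Kaempferol-4′-methyl ether,PPO,3HHS,−137.519
104,Naringenin-4′-methyl ether,PPO,3HHS,−137.451
107,"Isoscutellarein-8,4′-dimethyl ether",PPO,3HHS,−137.188
90,Forsythoside A,DmAChE,1DX4,−171.3
90,Forsythoside A,DmAChE,1QON,−254.5
88,Calceolarioside C,DmAChE,1DX4,−174.0
88,Calceolarioside C,DmAChE,1QON,−251.6
87,Verbascoside,DmAChE,1DX4,−178.8
87,Verbascoside,DmAChE,1QON,−233.5
89,Calceolarioside E,DmAChE,1DX4,−169.0
89,Calceolarioside E,DmAChE,1QON,−239.1
93,Calceolarioside D,DmAChE,1DX4,−162.3
93,Calceolarioside D,DmAChE,1QON,−227.7
92,Isoarenarioside,DmAChE,1DX4,−141.1
92,Isoarenarioside,DmAChE,1QON,−244.8
86,Calceolarioside A,DmAChE,1DX4,−156.2
86,Calceolarioside A,DmAChE,1QON,−212.8
91,Calceolarioside B,DmAChE,1DX4,−128.0
91,Calceolarioside B,DmAChE,1QON,−210.5
44,Isopimarane,DmAChE,1DX4,−119.9
44,Isopimarane,DmAChE,1QON,−180.3
43,Isopimarane,DmAChE,1DX4,−127.3
43,Isopimarane,DmAChE,1QON,−164.5
90,Forsythoside A,hAChE,4EY7,−177.7
90,Forsythoside A,hAChE,4M0E,−247.6
88,Calceolarioside C,hAChE,4EY7,−145.7
88,Calceolarioside C,hAChE,4M0E,−217.7
87,Verbascoside,hAChE,4EY7,−152.6
87,Verbascoside,hAChE,4M0E,−200.8
89,Calceolarioside E,hAChE,4EY7,−116.7
89,Calceolarioside E,hAChE,4M0E,−209.0
93,Calceolarioside D,hAChE,4EY7,−147.9
93,Calceolarioside D,hAChE,4M0E,−188.4
92,Isoarenarioside,hAChE,4EY7,−165.1
92,Isoarenarioside,hAChE,4M0E,−208.0
86,Calceolarioside A,hAChE,4EY7,−164.6
86,Calceolarioside A,hAChE,4M0E,−189.6
91,Calceolarioside B,hAChE,4EY7,−137.9
91,Calceolarioside B,hAChE,4M0E,−183.9
44,Isopimarane,hAChE,4EY7,−137.0
44,Isopimarane,hAChE,4M0E,−159.7
43,Isopimarane,hAChE,4EY7,−150.2
43,Isopimarane,hAChE,4M0E,−154.6
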
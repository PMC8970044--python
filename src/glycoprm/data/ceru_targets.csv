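peptide,glycan,charge,expected_rt_min,protein,glycosite
ELHHLQEQNVSNAFLDK,HexNAc(5)Hex(6)Fuc(2)NeuAc(3),3,32.5,CERU,762
ELHHLQEQNVSNAFLDK,HexNAc(5)Hex(6)NeuAc(3),3,31.8,CERU,762
ELHHLQEQNVSNAFLDK,HexNAc(4)Hex(5)Fuc(1)NeuAc(2),3,30.9,CERU,762
ELHHLQEQNVSNAFLDK,HexNAc(4)Hex(5)NeuAc(2),3,30.2,CERU,762
ELHHLQEQNVSNAFLDK,HexNAc(5)Hex(6)NeuAc(2),3,31.2,CERU,762
EHEGAIYPDNTTDFQR,HexNAc(4)Hex(5)Fuc(1)NeuAc(2),3,22.4,CERU,138
EHEGAIYPDNTTDFQR,HexNAc(4)Hex(5)NeuAc(2),3,21.7,CERU,138
EHEGAIYPDNTTDFQR,HexNAc(5)Hex(6)Fuc(2)NeuAc(3),3,23.1,CERU,138
EHEGAIYPDNTTDFQR,HexNAc(5)Hex(6)NeuAc(3),3,22.0,CERU,138
EHEGAIYPDNTTDFQR,HexNAc(4)Hex(5)NeuAc(1),2,20.8,CERU,138
ANHSGLYGSQVTK,HexNAc(4)Hex(5)Fuc(1)NeuAc(2),2,17.6,CERU,397
ANHSGLYGSQVTK,HexNAc(4)Hex(5)NeuAc(2),2,17.0,CERU,397
ANHSGLYGSQVTK,HexNAc(5)Hex(6)Fuc(1)NeuAc(3),3,18.3,CERU,397
ANHSGLYGSQVTK,HexNAc(5)Hex(6)NeuAc(3),3,17.8,CERU,397
ANHSGLYGSQVTK,HexNAc(4)Hex(5)NeuAc(2),3,17.0,CERU,397
ENLTAPGSDSAVFFEQGTTR,HexNAc(4)Hex(5)NeuAc(2),3,26.5,CERU,358
ENLTAPGSDSAVFFEQGTTR,HexNAc(5)Hex(6)NeuAc(3),3,27.2,CERU,358
ENLTAPGSDSAVFFEQGTTR,HexNAc(4)Hex(5)NeuAc(1),2,25.9,CERU,358
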
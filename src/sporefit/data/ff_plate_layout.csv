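well_id,substrate
A1,Water
A2,N-Acetyl-D-glucosamine
A3,N-Acetyl-D-mannosamine
A4,Adonitol
A5,Amygdalin
A6,D-Arabinose
A7,L-Arabinose
A8,D-Arabitol
A9,Arbutin
A10,D-Cellobiose
A11,alpha-Cyclodextrin
A12,beta-Cyclodextrin
B1,Dextrin
B2,i-Erythritol
B3,D-Fructose
B4,L-Fucose
B5,D-Galactose
B6,D-Galacturonic acid
B7,Gentiobiose
B8,D-Gluconic acid
B9,D-Glucosamine
B10,alpha-D-Glucose
B11,Glucose-1-phosphate
B12,Glucuronamide
C1,D-Glucuronic acid
C2,Glycerol
C3,Glycogen
C4,m-Inositol
C5,2-Keto-D-gluconic acid
C6,alpha-D-Lactose
C7,Lactulose
C8,Maltitol
C9,Maltose
C10,Maltotriose
C11,D-Mannitol
C12,D-Mannose
D1,D-Melezitose
D2,D-Melibiose
D3,alpha-Methyl-D-galactoside
D4,beta-Methyl-D-galactoside
D5,alpha-Methyl-D-glucoside
D6,beta-Methyl-D-glucoside
D7,Palatinose
D8,D-Psicose
D9,D-Raffinose
D10,L-Rhamnose
D11,D-Ribose
D12,Salicin
E1,Sedoheptulosan
E2,D-Sorbitol
E3,L-Sorbose
E4,Stachyose
E5,Sucrose
E6,D-Tagatose
E7,D-Trehalose
E8,Turanose
E9,Xylitol
E10,D-Xylose
E11,Tween 80
E12,gamma-Amino-butyric acid
F1,Bromosuccinic acid
F2,Fumaric acid
F3,beta-Hydroxy-butyric acid
F4,gamma-Hydroxy-butyric acid
F5,p-Hydroxyphenylacetic acid
F6,alpha-Keto-glutaric acid
F7,D-Lactic acid methyl ester
F8,L-Lactic acid
F9,D-Malic acid
F10,L-Malic acid
F11,Quinic acid
F12,D-Saccharic acid
G1,Sebacic acid
G2,Succinamic acid
G3,Succinic acid
G4,Succinic acid mono-methyl ester
G5,N-Acetyl-L-glutamic acid
G6,Alaninamide
G7,L-Alanine
G8,L-Alanyl-glycine
G9,L-Asparagine
G10,L-Aspartic acid
G11,L-Glutamic acid
G12,Glycyl-L-glutamic acid
H1,L-Ornithine
H2,L-Phenylalanine
H3,L-Proline
H4,L-Pyroglutamic acid
H5,L-Serine
H6,L-Threonine
H7,2-Amino ethanol
H8,Putrescine
H9,Adenosine
H10,Uridine
H11,Adenosine-5'-monophosphate
H12,D-Fructose-6-phosphate
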
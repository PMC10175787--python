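letter	name	broad_group
J	Translation, ribosomal structure and biogenesis	information storage and processing
A	RNA processing and modification	information storage and processing
K	Transcription	information storage and processing
L	Replication, recombination and repair	information storage and processing
B	Chromatin structure and dynamics	information storage and processing
D	Cell cycle control, cell division, chromosome partitioning	cellular processes and signaling
Y	Nuclear structure	cellular processes and signaling
V	Defense mechanisms	cellular processes and signaling
T	Signal transduction mechanisms	cellular processes and signaling
M	Cell wall/membrane/envelope biogenesis	cellular processes and signaling
N	Cell motility	cellular processes and signaling
Z	Cytoskeleton	cellular processes and signaling
W	Extracellular structures	cellular processes and signaling
U	Intracellular trafficking, secretion, and vesicular transport	cellular processes and signaling
O	Posttranslational modification, protein turnover, chaperones	cellular processes and signaling
X	Mobilome: prophages, transposons	cellular processes and signaling
C	Energy production and conversion	metabolism
G	Carbohydrate transport and metabolism	metabolism
E	Amino acid transport and metabolism	metabolism
F	Nucleotide transport and metabolism	metabolism
H	Coenzyme transport and metabolism	metabolism
I	Lipid transport and metabolism	metabolism
P	Inorganic ion transport and metabolism	metabolism
Q	Secondary metabolites biosynthesis, transport and catabolism	metabolism
R	General function prediction only	poorly characterized
S	Function unknown	poorly characterized
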
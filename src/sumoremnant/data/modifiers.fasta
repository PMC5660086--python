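>SUMO1 mature human SUMO1 (curated snapshot, precursor trimmed at C-terminal ...TGG)
MSDQEAKPSTEDLGDKKEGEYIKLKVIGQDSSEIHFKVKMTTHLKKLKESYCQRQGVPMN
SLRFLFEGQRIADNHTPKELGMEEEDVIEVYQEQTGG
>SUMO2 mature human SUMO2 (curated snapshot, precursor trimmed at C-terminal ...TGG)
MADEKPKEGVKTENNDHINLKVAGQDGSVVQFKIKRHTPLSKLMKAYCERQGLSMRQIRF
RFDGQPINETDTPAQLEMEDEDTIDVFQQQTGG
>SUMO3 mature human SUMO3 (curated snapshot, precursor trimmed at C-terminal ...TGG)
MSEEKPKEGVKTENDHINLKVAGQDGSVVQFKIKRHTPLSKLMKAYCERQGLSMRQIRFR
FDGQPINETDTPAQLEMEDEDTIDVFQQQTGG
>SUMO4 mature human SUMO4 (curated snapshot, precursor trimmed at C-terminal ...TGG)
MANEKPTEEVKTENNNHINLKVAGQDGSVVQFKIKRHTPLSKLMKAYCERQGLSMRQIRF
RFDGQPINETDTPAQLEMEDEDTIDVFQQQTGG
>Ub mature human ubiquitin monomer
MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYN
IQKESTLHLVLRLRGG
>Nedd8 mature human NEDD8 (curated snapshot, precursor trimmed at C-terminal ...RGG)
MLIKVKTLTGKEIEIDIEPTDKVERIKERVEEKEGIPPQQQRLIYSGKQMNDEKTAADYK
ILGGSVLHLVLALRGG
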
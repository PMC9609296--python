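# OTU assembly map: each OTU combines the morphology of one examined
# species with gene sequences of that species or a close relative.
# Columns: otu <TAB> partition <TAB> source_taxon <TAB> accession
# A row with empty partition/source marks a morphology-only taxon.
otu	partition	source_taxon	accession
Ashtoret lunaris	16S	Ashtoret lunaris	LK391941
Ashtoret lunaris	COI	Ashtoret lunaris	LK391941
Ashtoret lunaris	NADH1	Ashtoret lunaris	LK391941
Ashtoret lunaris	H3	Matuta planipes	KJ133142
Bathynectes maravigna	16S	Bathynectes maravigna	FM208770
Bathynectes maravigna	COI	Bathynectes maravigna	FM208770
Bathynectes maravigna	NADH1	Bathynectes maravigna	FM208814
Bathynectes maravigna	H3	Bathynectes maravigna	JQ305964
Calappa granulata	16S	Calappa granulata	KU206591
Calappa granulata	COI	Calappa granulata	KU206702
Calappa granulata	NADH1	Calappa bilineata	MN562587
Calappa granulata	H3	Calappa granulata	JQ306054
Callinectes sapidus	16S	Callinectes sapidus	AY363392
Callinectes sapidus	COI	Callinectes sapidus	AY363392
Callinectes sapidus	NADH1	Callinectes sapidus	AY363392
Callinectes sapidus	H3	Callinectes sapidus	FM208798
Cancer pagurus	16S	Cancer pagurus	FM207653
Cancer pagurus	COI	Cancer pagurus	FM207653
Cancer pagurus	NADH1	Cancer pagurus	FM208806
Cancer pagurus	H3	Cancer pagurus	JQ306000
Cancer irroratus	16S	Cancer irroratus	FM207654
Cancer irroratus	COI	Cancer irroratus	FJ581562
Cancer irroratus	NADH1	Cancer irroratus	FM208807
Caphyra loevis	16S	Caphyra loevis	KT365592
Caphyra loevis	COI	Caphyra loevis	KT365697
Caphyra loevis	H3	Caphyra loevis	KT425009
Caphyra rotundifrons	16S	Caphyra rotundifrons	KT365530
Caphyra rotundifrons	COI	Caphyra rotundifrons	KT365698
Caphyra rotundifrons	NADH1	Caphyra rotundifrons	KT365530
Caphyra rotundifrons	H3	Caphyra rotundifrons	KT424989
Carcinus maenas	16S	Carcinus maenas	FM208763
Carcinus maenas	COI	Carcinus maenas	FM208763
Carcinus maenas	NADH1	Carcinus maenas	FM208811
Carcinus maenas	H3	Carcinus maenas	FJ581597
Carupa tenuipes	16S	Carupa tenuipes	FM208758
Carupa tenuipes	COI	Carupa tenuipes	FM208758
Carupa tenuipes	NADH1	Carupa tenuipes	FM208789
Carupa tenuipes	H3	Carupa tenuipes	KT365703
Catoptrus nitidus	16S	Catoptrus nitidus	FM208755
Catoptrus nitidus	COI	Catoptrus nitidus	FM208755
Catoptrus nitidus	H3	Catoptrus aff. nitidus	KT365706
Chaceon mediterraneus	16S	Chaceon granulatus	FM208775
Chaceon mediterraneus	COI	Chaceon granulatus	FM208775
Chaceon mediterraneus	NADH1	Chaceon granulatus	FM208827
Chaceon mediterraneus	H3	Chaceon granulatus	AB769383
Coelocarcinus foliatus	16S	Coelocarcinus foliatus	KT365601
Coelocarcinus foliatus	COI	Coelocarcinus foliatus	KT365724
Coelocarcinus foliatus	NADH1	Coelocarcinus sp.	KT365545
Coelocarcinus foliatus	H3	Coelocarcinus foliatus	KT425058
Corystes cassivelaunus	16S	Corystes cassivelaunus	FM208781
Corystes cassivelaunus	COI	Corystes cassivelaunus	FM208781
Corystes cassivelaunus	NADH1	Corystes cassivelaunus	FM208801
Corystes cassivelaunus	H3	Corystes cassivelaunus	JQ306005
Eriocheir sinensis	16S	Eriocheir sinensis	KP064329
Eriocheir sinensis	COI	Eriocheir sinensis	KP064329
Eriocheir sinensis	NADH1	Eriocheir sinensis	KP064329
Eriocheir sinensis	H3	Eriocheir japonica	KJ133099
Libystes nitidus	16S	Libystes nitidus	FM208762
Libystes nitidus	COI	Libystes nitidus	FM208762
Libystes nitidus	H3	Libystes nitidus	KT365728
Liocarcinus depurator	16S	Liocarcinus depurator	FM208767
Liocarcinus depurator	COI	Liocarcinus depurator	FM208767
Liocarcinus depurator	NADH1	Liocarcinus depurator	FM208819
Liocarcinus depurator	H3	Liocarcinus depurator	JQ306013
Liocarcinus navigator	16S	Liocarcinus navigator	KU560476
Liocarcinus navigator	COI	Liocarcinus navigator	KP795939
Liocarcinus navigator	NADH1	Liocarcinus navigator	FM208821
Lissocarcinus orbicularis	16S	Lissocarcinus orbicularis	FM208757
Lissocarcinus orbicularis	COI	Lissocarcinus orbicularis	FM208757
Lissocarcinus orbicularis	NADH1	Lissocarcinus orbicularis	FM208791
Lissocarcinus orbicularis	H3	Lissocarcinus orbicularis	KT365732
Macropipus rugosus	16S	Macropipus tuberculatus	FM208769
Macropipus rugosus	COI	Macropipus tuberculatus	FM208769
Macropipus rugosus	NADH1	Macropipus tuberculatus	FM208815
Macropipus rugosus	H3	Macropipus tuberculatus	JQ306218
Medorippe lanata	16S	Medorippe lanata	EU636950
Medorippe lanata	COI	Medorippe lanata	EU636981
Medorippe lanata	H3	Dorippe quadridens	KJ133093
Necora puber	16S	Necora puber	FM208771
Necora puber	COI	Necora puber	FM208771
Necora puber	NADH1	Necora puber	FM208813
Necora puber	H3	Necora puber	FJ755619
Ovalipes ocellatus	16S	Ovalipes punctatus	FM208824
Ovalipes ocellatus	COI	Ovalipes punctatus	MH802052
Ovalipes ocellatus	NADH1	Ovalipes punctatus	MH802052
Parathranites orientalis	16S	Parathranites orientalis	KJ132616
Parathranites orientalis	H3	Parathranites orientalis	KJ133173
Pirimela denticulata	16S	Pirimela denticulata	FM208783
Pirimela denticulata	COI	Pirimela denticulata	FM208783
Pirimela denticulata	NADH1	Pirimela denticulata	FM208808
Polybius henslowii	16S	Polybius henslowii	FM208765
Polybius henslowii	COI	Polybius henslowii	FM208765
Polybius henslowii	NADH1	Polybius henslowii	FM208816
Polybius henslowii	H3	Polybius henslowii	JQ306293
Portumnus latipes	16S	Portumnus latipes	FM208764
Portumnus latipes	COI	Portumnus latipes	FM208764
Portumnus latipes	NADH1	Portumnus latipes	FM208812
Portunus inaequalis	16S	Portunus inaequalis	FM208752
Portunus inaequalis	COI	Portunus inaequalis	FM208752
Portunus inaequalis	NADH1	Portunus inaequalis	FM208795
Portunus inaequalis	H3	Portunus pelagicus	KR153996
Raymanninus schmitti	16S	Raymanninus schmitti	KT365560
Raymanninus schmitti	COI	Raymanninus schmitti	KT365560
Sternodromia monodi	16S	Lauridromia dehaani	AY583899
Sternodromia monodi	COI	Lauridromia dehaani	EU636986
Sternodromia monodi	NADH1	Lauridromia dehaani	MT038417
Sternodromia monodi	H3	Lauridromia dehaani	KJ133125
Telmessus cheiragonus	16S	Telmessus cheiragonus	FM207656
Telmessus cheiragonus	COI	Telmessus cheiragonus	FM207656
Telmessus cheiragonus	NADH1	Telmessus cheiragonus	FM208802
Telmessus cheiragonus	H3	Telmessus cheiragonus	KX039796
Thia scutellata	16S	Thia scutellata	FM208782
Thia scutellata	COI	Thia scutellata	FM208782
Thia scutellata	NADH1	Thia scutellata	FM208810
Thia scutellata	H3	Thia scutellata	KT209396
Varuna litterata	16S	Varuna litterata	MW125542
Varuna litterata	COI	Varuna litterata	MW125542
Varuna litterata	NADH1	Varuna litterata	MW125542
Varuna litterata	H3	Varuna litterata	FN434060
Xaiva biguttata
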
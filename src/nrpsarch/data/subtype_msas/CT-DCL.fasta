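>CT-DCL_0
RWGRMYISQWQGMNVQMLMRSRASVRLWFLRRRCKVRNLQECLGMYMKPTSSQQYIPRED
RHETLGTNFRLGFPEFGFTTKHPRAIWFSSALHFEPPRDKEIGHVMDWDMHHYISSGVSS
WGGWESDYFKAMEHAVDIISLWHINRQNATSSYEDHLPQSKFQQWDVEYYIDDAVEYTME
DDESSWDSQCFMVMLKVLCIKERDHMAAWLDDRWIPSMLPVWYYMHTDPMISNISCHDCC
DIGNFVNTLATRCEVMTTCQEYSMCCSKFKHTLDDACRCARKFEFGEGSYRPQNCDEHQD
VPFEDSHNGHPHEMFVDCIDVQYAQLNWWPTFILMDAYLWYDGCCNHQWVFHCHYMMYRE
SKWVRDYSRNPLHLIKCDFYCTLCMLFVMLELTTHHMVCEHYCSDQYIRCMS
>CT-DCL_1
RWARFYISQWQGMPVQMLMRSRAQVRLWFLRRRCKVRNLQECLGRYMFPTSSQQYIPRED
RHETNRTNKRLGFPTFGPTTKHPRAIWFVSAHHFEPCRDKEIGHVMDWDMHHYIHDGVSS
WMVWKSDNFKIMEHAVDIISLLHCNRQKATSSYEDKLPQSKFQQWDVEYYIDFAVWYTME
DDESSWDSQCFMDLLKQLCIKERKHMAAWLDDRWIPSMLCIWYYMMTDFMKSNISCHNCS
DIGNFVNTLATRPGVMTTCQEKEMCCSKEKHTLYDACRVARMFEFVEGSYRPHNCDVWQD
VPFEDSHNGHTHEMFVDRPDVIYAQLNWWPNFILMMKYLWKDGCCKHQRVCHCHYMVDRE
SKSVRRYSRNPLHLKKCVEYCTLCMLFVELELTTHHMVCEHYCSDQYIRCMS
>CT-DCL_2
RWGRMYISQWQGMPVQFLMRSRAQVRHVFLRRRCKVRNLQECLGRYLFPLSWQQYIPRED
RLETLRTNFRLGFPTFEFTTKHPFAIWFSSALHFEPPRDKEIGFVMDWDMHHYISDWVSS
WDGWVSDTFKIMEHAVDIISLLHCNRQKATSSYEDHITQSKFQQWDMEYYIDFAVWYTVE
CDESSWDSQCQMDMLKQLDIKERDHGQAWLDDRWIPSMLCIWYYMHTDFMKSNISCHTCC
DIGNFVNTLATRCGVLTFCQEKEMCCSKFKHTLDDACRCARMEEFGEGSYRPQDCDEHQE
VPFHDSHNGHKHEMFVDCPDVQYAQLNWWPEFILMMAYLWYDGCCKHQWVCHCHYMMDRE
SKWVRDYSRNPLHLKKCVFYCTLCMLFSDLELTTHHMVCEHYCSDQYIRCMS
>CT-DCL_3
RWGRMYISQWQGMPVAMLMRSRAQKRLWFLRRRCKVRNLQEFLGRYMFPTSSQQYIPRED
RHETRRTNFRLLFPTFGFTTKHPRAIWFSSWLHFEPPREKWIGHVMDWDMKKYISDGNSS
WGGWKSDYFKIMEHAGDIISLLQCNRQKRTSSYEDKLKQVIFQQWDVEYMCDFYVWYTME
DDESSWDSHCFMDMLKQLCVHERDHMAAWLDDRVIPSMLCIWYYMHTDFMKSNISCHTCC
DIGNFVNTLAPIQAVMTTCQEKEMCCSKFKHTLDDPCRCARMFEFSIGSYRPQNCDEHQD
VQFEDSHNGHTHEMFVDYPDVQYAQLNWWPNFILMMAYLWYDGCCKHQGVCHCHYMRDRE
SKWVRDYSRNPLHLKKCVFYCNLCMLFVDLELTTHHMVHEHYCVDQYIRCMS
>CT-DCL_4
RWGRMYISQWQGMPVQMLMRSRAQKRLWFLNRRCKARNLQECLGRKMFPTSSQQNIPRGD
RHETLRTNDRLGFPTFGFTTKHPRAIWFSSALHTEPPRDKEIGHVMDWDMHHYISAGVQS
WGGWKSDYGKIMEHAVDIISLLHCNRQKATSSYEDHLPQSKFQMWDVEYYIDFAVWYTME
DDESSWDSQCFMDNLKQLCIKEIDHMAAWLDMRWIPSMLCIWYYMHTDFMKSNISCHTCC
DIGNFVNTGACRCGVMTTCQEKEMCCSKFKHTLDDACRCARHFEFGEGSYRPQNCDEHQG
VVFEWSHNGHTHFMFVDCPDVQYAQLNWWPNFILMMAYLWYEGCCKHIWVCHCHNMMFRE
SKQVRDYSRNPLHLKKCVFYCTLCMLFVDLYQTTHHMVCEHYCSDQYIRCMS
>CT-DCL_5
RWGRMYISQWQGMPVVMLMRSRAQVRLWFLRRRCKVRNLIECLGRYMFPTSSQQYIPRED
RHETLRTNFRLEFPHFGFTTKHPHAIWFKSALHFEPPRDKEIGHVMRWDMHHYISDEVSS
WGGWKSDYFKIMEHGVDIISLLHCNRYKATSSYLDHLPQSKFQQWDVSYYIDFAVWYTME
DDESSWDSQHFDHMLKQLCIKERTHMAAWLDDRWIPSMLCIWYYMHLDFMKSNISCHTCC
DIGNFVNTLATRCGVMTTCQEKEMPCSKFKHTQDDACRCARMFEFGEGSYRIQNCDEHQD
VPFEDSHNMHTHEMFVDCPIVQYAQLNWWHNFILMMEYLWYDGCCKQQWVCHCHYMMDRE
SKWVRDYSRNVLHLKKDVFYCTLCMLFVDLELTTHHMVCEHYCSDQYIRCMS
>CT-DCL_6
RWGRMYESAWQGMPVQMLVRSRAQVRLWFLRRRCKVRNTQECLGRYMFPHSSQQYIPRED
RHETLMTNFRLGFPTFGFTTWHPRAIHFSSALHFEPPRDNEIGHVMDWDMHHYQSDGVSS
WGGWKSDYFKIMEHAVDIISLLHCFRQKATSSYEDHLPQSKFQQWDVEYYIDRAVWYTFE
DDESSIDSQCFMDMLKQLCIKERDHMAAWTDDRWIPKMLCIWYYMHTDFMKSNISCHTCC
DIGNIVKTLATRRGVMTTCQEKEMFCSKFKHTLDTACRCARMFEFGEGCYRPQNCDYHQD
VPFEDSHNGHTHEMFVDCPDVQHAQLNWWPNFILMMAYLWYDHCCKHQWVCHCHYMMDYE
SKWVRDYSRNPLHLKKCVFYGTLCMLFVDLELTTHHMVCEHYCSDQYIRCMS
>CT-DCL_7
YWGRMYISQWQGMPVQMLMRHRAQVRLWWLRRRCKVRNLQECLGRQMFPTSSQQYIPRED
HHETLRTQFRLGFPTFGFGTKHPLHIWFSSALHFEPPRDKEIGHFMDWDAHHTISDGVSS
WGGWKSHKHKIMEHAEDIISLLHCNRQKATSSYEDDLPESKLQQWDVEQYIDFAVWWTME
DDESSWRSQCFMDMLKQLHIKERDHMAAWLMYRWIPSMECIWYYMWTDFMKSNIYCHTCC
DIGLFVNTLATRCGVMTTCQEKEMCCSKFKHTFDDACRCASMFEFGDSSYRPQPCDEHQD
VPFEDSHNGHTHEMFVDCPDVQYAQLNEWCNFILMMAYLWYDCFCKHQWVCHCHYMMVRE
FKWVRDYSRNPLHLKKPVFYCTLCMLFVDLELTTHHMVCWHYCSDQPIRDMS
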
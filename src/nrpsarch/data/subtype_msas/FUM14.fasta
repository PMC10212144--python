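>FUM14_0
RKATTVQKSTEDHGNNFDAASAKQGRLWVLNEHGHGTAIDMSWVHREARIVHTMFYVMTA
RHEYLRTAFNDDQPLGIHQAMWTTPGCNYYCELFFYPKWCWCCYDFMMIMHLNISDGVSA
ANGFEQPDNTMGKETAENYKHSHMCVPTRSNCMTKVFCDRLGYMWIEGAYYDAAVWERSL
FAWKIMLENWPRRDTRPPLKNVKNFDARSMLAWGIMIRHKLINEAILQTWANASPIGVLY
DIGKFVNTLAVEWTAHVMRWCQRSRDHQCPVPPSWLDLNIMDFRTMMMVSAWCSCYMHQD
VPFEHEIMDVEDNDHERIKLMATDDILTFFGKPIWYSGPGLWVYPVGWNKRMLAITGGES
VARSRDQSWDCLQDGNSFWRQCFIDPVMMEFSKIPQDSLKEGWDYHFACFRH
>FUM14_1
RKQTTVNKSTEDHGNNFAAASAWQGHLWVLNEHGHGLAIEMSWVHREARIVETMFYVMTA
RHEYLRTAFNMDQPLGIHQAMWTTPGCCTYCELFFYPKWDVCCRDFMMIMHHNIMDGKSA
ANGFTPPDQTMGKETAEAYKHSYMCVPTRSNPMFDVFCDRLGYMWIYNAYPDFAVWESSL
FAWKGMLENWPRRDLRPPLKNVKNDDARSMLAWSIMIRHKAINEAIRQTWANGSPIGVLY
DIGAFVNTMAVDWTAHVSRWCQRSRDHQCPVPPSWPDLNIMDFRTQMMVIAWHSCYMHQD
VPFEHEIMDVEWNDHIRITLMHTDDILDFFGKPIWQSGAQLWVYPVGYNKCMLAITGGES
VARGRDQSRNPLQDGNSFWRQCFIDPRMGEFQKIPSDSLKEGWQRHFACFRH
>FUM14_2
RKATTHNKSTEDHGNNFDAASAAQGRLWVLNEKGHGLAIEMSWVHREARIVETMFYVMTA
RHEYLRTAFNMDQPLGIMQAMWTTPGCNTYCDLFFYPAWDVCCRSFMMIMHHNISDGVSA
ADGFEPPDRTMGKETAERYKHSHMCVPTRLFPMFDVFCDDLGYMWIENAYPDFAVWESSL
FAWKGMLENWPRRDLRPPLKMVKNFDARSMLAWCIMIRHALINEAILQTWANASPIGVLY
DIKAFNNTLACRWTALVSRWCQRNIDHQCPVPPSWPDLNIMDFRTQMMVIAWCSCYMHQD
VPFEHEIMDVEDNDHERITLMATDDILDFFGKPIWYSGPLLWVYPVCYNKRMLAITSGES
VARSRDQSRNKLQDGNSFWRQCFRFPRMMEFAKIPQDSLKEGWQRHFKCFRH
>FUM14_3
RKATTVNKSTEDHGNNFDAASAAQGRLWVLNEHGHGLKIEMSWVHREARIVKTMFYVCTA
RHEYLRTAFNMDQPLGIHQAMWTTPPCNTYCELFFYPKWPVCCRDFMMIMCHNISDGVSA
AGHFEPPDNTMGKETAENYKHEHMCVPTRSNPMDDVEVDRLGYMWIENAYPDFAVKESSL
FAWKGMLENWPRRDLRPPLKNVKNYDAWSMLAWGIMILHELINGAILQTWANASPIGVLY
DIGAFVNTLAIRWTAHVSYWCQRSRDHQCPVPPSWPDLNIMDFWTQMMVIAWCSCYMHQD
VPFEHEIMDVEDFDHERITLKAYDDILDFFGKWIWYSGNQGWVYPVGYNKRMLAITGGES
VARSRDQSRQPLQDGNSFWRQCFIDPRMMEFAKIPQDSLKEGWQRHFACERH
>FUM14_4
RKATTVNKWTEGHGNNFDAASRAQIRLWVLAEHGHGRAIEMSWVHREARIVETMFYVMTA
RHEYLRTAENMDQPLGIHQAMWTTPGCNTYCEDFFRPKWDVCCRDFMMIMHHNISDGVSA
ANGFEPPDNTMGKETAENCKHSHMCVPTRVNPMFDVFCDRLGYMLIENAYPDFAVWESSL
HCWKGMLENWPRRDVRSPLKNVKNFDARSMLAWGIMIRQELINEAILQTWANASPITVLY
DIGAFVNTLAVRWTAHVSRWCQRKRDHQCPETDSWPDLNIMDRRTQMMVIAECSSYMHQD
VPFEHFIMDVEDNDHERGTLMATDDILDFFGKPIWYSGPELWVYPQGYNKRMLAITGGQS
VARSRDQSRNPLQDGNSFWRQCFIDPRMMEIAKIPQCSLKQGWPRHFACFRH
>FUM14_5
RKATCVNKSTEAHGNNFDAESAAQGGLWVLNEHGHGLAIEMSWVHREARIVETMFIVMTA
RHEYLVTAFNMDQPLGIHQAMWTTPGCNTYCELFFYPKWDMCCRDFMMIMHHTISDGVSA
ANGFNPPDNTMGKETAENYKHSHMCVPTRVNPMFDMFCDRLGYMWIEMAYPDFAVWESSL
FAWKGMFWNWPRRDLRPPLKNVKNFDARSMHMWGIMIRHKLINEAILQTWANASPIGMNY
DIGAFVNTLAVRWTEHVSRWCQRSRDHDCPVPPSWPDLNHMDFDTQMMVIAWCSCYMHQK
EPFEHEIMDVEDNDHERITLMATDDILDWFGKPIWYSGIQLWVYPVGYNKRMLAITGGEL
VARARDQSRNPLQDGQSFWRQCFIDPRMMEFVKIPQDSLKEGEQRHFACVRQ
>FUM14_6
RKATTVNKSTEDHGNNFDAASAAQGRLWVLWEHGHGLAIEISWVHREARIVETMFYVMTA
RHAYLRTAFNMDQPLGIHQAQWTTPGCNTYCELFFYPKWDVCCRDFMMDMHHNISDMVSA
ANGFEPPDNTMGKETAENYKHSHMCVPTRSNPMFDVFCDRLGYMWIKNAYPDFAVWESSL
FAWKGMLTNWPRWDLRPPLKNVKNFDAASMLASGIAIRHKLINEAILQTWANASPIGVLY
DIGAFVNTLAVRWTAHVSRWLQRSRDHQCPVPPSWPDLNIMDFRTQMMVIAWCSCYMHQD
VPFEHEIMHVEDNDHERITLHATDDILDFFGKPIWYSGPQLWVYPVGYNKRMLAITGGES
VALSRDQSRNPLQDGNSFWRQCPIDPRMMEFAKIPQDSLKEGWQREFAEFRH
>FUM14_7
RKATTVNKSTERHGNWFDAASAAQGRLWVLNEHGHGLAIEMSWVHREARIVETMFYVMTA
RHEYLRTAYNMDQPLGIHQAMWTPPGCNTYCELFFIPKWDVCCRDFMMIMHHNISDGVSF
ANGFEPPDNTMGKETNENYKHGHMCVPTRSNPMFDVFCDILGYMWIENAYPDFAVWRSSL
FAWKGMLENWPRRDTRPPHKNVKNFDARSMLAWGIMIRHKLFNDPILQTWAQASPIGVDY
DYGAFVNTDAVRWTAHVSRWCQRSRDHQCPVPPSWPDLNIMDFRTQMTVFAWCSCYMHQD
VPFEHEIMDVEDNDHERITLMATDGILDFFGKPIWYSGGQLWVYPVGYNRHMLAIFWGES
VARSRDTSRNRLADGNSFWRPCFIDPRMMEFKKIFQDSLKEGWQRHFACFFH
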
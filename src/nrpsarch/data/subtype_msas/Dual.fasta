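>Dual_0
IYSMWMIQYTYVWSFWVKYWSYAQKRLWALYIIARYHRCHGCVDLMATGEWFDNAPSWDI
RHELLRTKFGWVQKSEIDIKAGYCTHRPDWFAIGNMLTIFGWSREGEMIMHHRQSDGVSE
DKYFMWATYNHNMGQGDIPCSDKMGLWAETIWTFALAFPDLEYPYTDTPYLDFNVWVCDK
VFLKDLWKEMIGTHATQAGQMRENLPQECNDMMLSDVAMHFMARCDASMVCPKESKEPFW
HIGKFVNTLAHFHWLKCFIRANCEFALVSNIDTPHRRSSAPFKVIGIDCFNNSVAWHHQD
VPFEFFMEHCKDEPYKTFCCVQGTHVYVMQYGRNSHEFCFAGFPSVKIELADQYRGHKMA
RMCIRDNSRNPLVFGMYPTVALVGVSMTMHWKILATCMYEISSFGSYHDHAI
>Dual_1
IYSMPEIQYTYVWSFWVKYTSYALKRPWALYIIAYYHRCHGCVDLMLTGEWFDNAMSWDI
RPELLRTKFGWVQKSEIDLNAGYCFHRPDWFAIGNMLTIFGGSREGEMIMHHRISDGCSR
DKYFMWATYNHNMGPGDDPCSDKMGLWAERIWTDALAFPDLEYPYSWTPYLDFAVWVGDK
VRLKDLWKEMIGEHKTQAGQMRENLPQECPDMMQSDVAMHFMFRLDASDVCVKESKEPFW
HDGKFVNTLAHRHHLKEFIRANCEFALVSNIDTLHRRSSAPAQVIANDCFNNSVAWHHQD
VPFEFFWEHCKDTPFKTFCCVQGTHVYVMQYGRNSHWYCFAGFPSVKIELADQYRGHKMA
RMCIRDNSRNPNVFGMYPTVALVGPSMTMHWKILATCMYEISSFGSYHDHAI
>Dual_2
IYSDREIQYTYVWSFNVKYWSYAQKRLWALNIIADYHRCNGCVDLMLTGEWFDNAMSWDI
YHELQRTKFGWVQKSEIDLNAGYCFHRPVWFAIGNMLTIFGGSRRGEMIHHHRISDGVSH
DKYHMWATYNHCMGQGDIPCSDKMGLWAERINTCALAFPDLEYPKTWTPYLDFAVWVCDK
VRLKDLWKKMYGTHKTQAGQMRENLPQECNDMMQSDVAMHGMFCLDASNVCPKESKEPFW
PISGFVNTLAHRHHPKCFIRANCEFALVSMIDTLHRRSSAWAMVIALDCFNNSVAWHEQD
WPFQFFWEHCKDEPYKTFCCVQMMHVYVMQYFRNSHEYCFAGFPSVKIELADQYSRHKMA
RMCIRDNERNPLVFGMYPTVAMVGPSMTMHWKILATCMYEISSFGSYHCHAL
>Dual_3
IYSMREIQYTYVWCFWVKYGSGLQKRLPALYIIARYHRCHGPVDLMLTGEKFDNAMSWDI
RHEHLRTKFGWVQKSEIDLNAGYCFHRSDWFAIGNMLTIFGGSREGEMIMHHRISDGVSM
DKYFMWATYNHNMGQGDIPCSDKMGLWDETIWTFALALPWLMYPYTWTPYLDFRVWTCDK
VRLKDLWKEMIGTHKTQAGQMRENLPQECNDMMQSDVAMHFMFRLDYSDVCPKESKEPFI
HIGKFVNTLHHRHHLKCFIRANCERALVSEIDTLHRRSSAPAQVIANDCFNHSVAWHHQD
VPFEFFWEHCKDEPYKTFCCVQGGHVYVMQYGRNSHEYCFAGFPSVKIELNDQYHGHKMA
RMCIRDSSRNPLTFGFYPTVALGEPSMTMHWKILATCMYEISSTGSYHDHAI
>Dual_4
GCSMREIGYTYVWSFWRKYWSYAQKRLWALYIIARYARCHGCVDLMLTGYWFDQAMSWDI
RQELLRTKFGWVQKSDIDLNAGYCFHRPDWFAIGNMLNIFGGAREGEMIMHHRISDGVSM
DKYFMWATYNHNMGQGDIPCSDKMGLWAERIWTFALAFPDLEYPYTWTPYLDFAVWVCDK
VRLKDLFKEMIGTHKTQAGQMPENLPQECNDMMQSDVAMHFDFRLQAMDVCPKESKEPFW
HIGKFVNTLAHRHWLKCFIRANCEFALHSNIDTLHRRSSAPAQVIANDCFNNDVAWHHQD
VPFEFFWEHCKDEPYKTDCWVQNTHVYVMQYGRNSHEYCFAGFPSVKITLADQYRGHKMA
RKCIKDNSRNPLVFGMYPTVAAVGPSMTMHWKILATCMYEISSFGSYHDHAI
>Dual_5
IYWMGEIQYTYVWSFWVKYWSIAQMRLWALRIIARYHRCHDCVDNMLTGEWFDNAMSWDI
RHELLRTKFGWEDKSEIDYNAGYCFLRPDWFAHGNMLTIFGGSREGRMIMHHRIEDGVSM
DKCFMWANYNHNMGQGDEPCSDKMGLWAERIWTFMLAFPDLEYPYTPNPYLDFAVWVCDK
VRLKYLWKEMIGTCKTQAGQMRENLPWECNDMMQSGVAMHFMFRLDRSDVCPKESKEPFW
HIGKFVNTLAHRHHFKCFIRANCEFALVSNINTLHRRSSAPAQVIANDCFNNSVAWRHQD
VPFEGMWEHCKDEPYKTGRCEQGTHVYVMQYGRNSHEYCFAGFPSVKIRLADQYRGHKMA
RMCIRDNSRNPLVFGMYITVALVGNSMQMHWKILATCCYEWSSRGSYHDLAI
>Dual_6
IPSMREIQKTYVWSFWVHYWSYAQKRLWALYIIARYHECHSCVDLALTGEWLDNAMSWDI
RHELLRTSFGGVQKSEIDLNAGYCFHRPDWFGLGNMLTIFGGSCAGEMIMHHRISDGVSM
DKYFMWATYNHNMGQGDITCSDKMPLPAERIWTFALAFPDLEYTYTWTPYLDFAVWVCDK
VRLKDLWKEMIGTHKTQAGQMRENLLQPCNDGMQSDVAMHFMFRKDASDVCPKESKEPFG
HIGKFVATLAHRHHLKCFIRANCEFHLVSKIDTLHRRSSPPAQIIANDCFNNIVAWHHQD
QPFEFVWEHCSDEPYATFCDVQGTHVYVMQYGRNSHEYCFDGFPSVKIELADQYRGHKMA
RMLIRDNSRNPCVFGMYRTVALVEPEMTMHWKILATCMYEKSSFGSYHDHAI
>Dual_7
IYSMREIQYTYVWSFWVGYWSYARKRLWAEYIIARYHRCHGCVDLILTGEWFDCAMSWDI
RHELLRTNFGIVQKSEIDLNAGYCFHRPDWFAIGNMLTIFGGYREGEMIMHHHIQDGVGM
DKYFMWATYNHNMGQTDIPCSDKMGLWAERIITFALAFPDNEYPYTWTDYVDFAVWVCQK
VRLKDLWKEMIGTHKTQAGQLRENLPQECNNMMQSDVAMHFMFGLDASDVCPKESKEPFW
HIGKFVNTCAHRHHLKWFIRANCEFALVSNIDTLHRRSSAPKQVIAHDCFNNSVAHHHVA
VIFEFFWEHCKDEPYKTSCCVQGTHVYVMVYGRNSHEYMFAGFPSVKIELADGYRGHKMT
RMCIRDNDKQPLVFGMYPTVALVGPSMTMHWKILATCMYEISSFGSYHDHAI
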
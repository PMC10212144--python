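>Cglyc_0
INRHCRASDDHYERIGSCWQSMAQDNLVTLRCIFDVIVIACAPVKYVRWMRCHEKKRFIY
RHEHLRTCFIGYQGMHRSELICKSANMHFVAMLVGRQSCQVDICGCSEDMLHPISDGVSE
PYNIVVFGYGSQVNWYYCENKDHYAFNGLWSSYQKAGQDFEAVELEKVWYVDFAVWPTMG
TDDCQYNPYNGWHWVTGGDQDWTSMWHKDSEQVLAFIHQHGINVIWTSYHGPVKTQHFDN
EIGPFVNTLAYRNYHHTGDIECDDFVTGWVTDIKHMHQEVPMGVEHFHPTSMHIIRYHQD
VPFEMLVHHKKVPLCNWFMENMMQFMEVDIPKFYPRNSLNEHHDNYPSREELQKEFVCSQ
TYDRRDLSRNPLTEESYIDGQVWTDYDPMKPSHDAYNYMRFDATWCLNRGLL
>Cglyc_1
IIRHCQASDDHYERSHSCWQSMAQDRLWTLRCIFDVIDIACAPVKYARWMRWHEKCRFIY
RHEHLCTGFIGYQTVHRSELICKSFNMIFPAMLVGRNSCQVDICGCSEDMHHPISDYVSV
EYNIVVFGYGSQVNHVYCENKDHYAFNGLWSSYQKAGQDFEAVELEKVWYVCFAVKPTLG
TDDCQLNPYQGWHWCTVGDQDWTSMEAKDSEQVLAFIHAHGINVIWTSWHGPVYQNHFDN
EIGPFVNTLAHRNYHHTGDIECDDFVTGWVTDIKHMHQEVPMIVNHFDPTRMHIQRYHQD
VPFQMLVHHKYVILAQWEMENMMQFPEVDIPKAYPRNKCNEHHDNYQVREELQKGFVCSF
TYDRRDLSRNPLTEESYIKGQVWTDYDPHKPSHFAYNIMEFDATCCLNRGLL
>Cglyc_2
INRHCQASDDTYEGSGSCWQSMAQDRLWTLRCIFDVCDIACAPVAYARWMMRHEKKQFIY
RHEHLRTGFIGYQGMHRRELICKSFMMIFVASLVGRQSCQVDICGWSEDMHHPISDGVSV
EYNPVAFGYGSQVNHVYCENKDHYAFNGLWSSYFKAGVDGEAVLLEKVWYVDKAVWPTMG
TDDCQYNPYNGWHWCTGGMQDWSSMEAKDSEKVLAAIHAHGINVIWTSWHGPVYQNHFDN
EAGPFVNTYAYRNYHHHGDIECSDFVTGWVTDIKHMHQEVAMGVEHFHPTSMHIIRYHQD
VPFEMLVHHKYVPLCKPFLENMMQQPRVDIPKDYPRNSLNEHHNNYPVREEFQKGFVCSQ
TVDRRPLSRNPLTEESYIVGQVWSDYDPHKPSHDAYNIMRFDDTCVLNRGDL
>Cglyc_3
INRHCQASDDHYKTSGSCDQSMAQDRLWTFRCIFDVIDIACAPVKYAIWMRWHEKKRFIY
RHEHLRTGFIGYQGMHRIELICKSFNMIPVAMLVGRSSRQVDICGCSEDIHHPISDQVSV
EYDIVVFGYGSQVNHVYCENKDHYAFNGLWESYGKAGQLFEAVYLEKVWYVDFAVWPTMG
TDDCQYNPYNGWNWCTGGDQDWTSMEAKDHEQVLAFIHAHGYSVIWTSWHGPVYQNHFDN
EIGPFVNTLAYRNYHYTGDIECDDKVTGWVVDIQHMHQNVPMGVEHFHPTSMHIIRYHQD
APFEMLVHHKYVPLCQWFMEVMMQCPEVDIVKFCPRNSLNEHHDNYPVQEELQKGFVCYQ
TWDRRDLSRGPLTEESYIKGQVITDYDPHKPMHDAYNIMRFDATCCLNRGLL
>Cglyc_4
INRHHDASDPHYERSGSCWQSMAQDRLWTLRCIFDVIMIACAPVKYARWMEWHEKKDFIE
RHEHLRTGFIGSQGMHRSELICKSFNKIFVAMVVGRQSCQVDIKGCCEDMHHPNLDGVSV
ESNIVVGWYGSQVNHYYCENKDHYAFNGLWSSYQKAGQDFPAVELEKVWYVDFAVWPTMG
TDDNQYNPYNGWHWCTGGDQDWTSMEAKDSEQVEAFIHAHGINVIWTSWHGPVYQNHFDN
EIGHFVNTLAYRNCHHPGDIECDDFVTGWVTDIKHMHQEVPMGVEHFHPTSMHIIRYHQD
GPFEMLVVHKNVPLCQWFMENHMQQPEVDIPKFYPRVSLNEHHDNYPVREFLQKGVVCSQ
TYDRRDLSRNPLTEECYIKGQVWTDYDPHKPSHDAYNTMRFDATCCLNRGLL
>Cglyc_5
INRHCQAHDDQYERSGSCWQSMANDRSWTLRCIFDVIFIACAPVKYMRWMRWHEKFRNIY
RHEHLRTGFIGYQGMLRSELICKSFMMIFVAMDVGRQSCQVDICVCSEDMHHPISDGVSV
MYNWVPFGYGSQVNHVYCENKDHYAFNGLWSSYQYAGQDFEAVELEKVWYVDFAVWPTMG
TDDCRYNPYNGRHWCTGGDQDWTSMEAKNSEQVLAFIHAHGFNVIWTSWHGPVYQNHFDN
EIGPVVNTLAYREHHHTGQIECDDFVTQWVTDIKHSCQEVPMGQEHFHPTSMHIIRYHQD
VPFEMLVHHKYVPLCEWFMENMMQQPEVDIPKFYPRNSLNEHHDNYPVREEGQKGFVCSQ
TYDRRDLSRNPLTCESYIKGQAWTDCYPHKPSHDAYWIMRFDATCCLNRGLL
>Cglyc_6
IARHCQASDDHYERSGSEWQSMAQIRLSTLRCIFDVIDIACSPVKYARWMRWHEKKRFIG
RHEHLRTGFIGYHGMHRSELICKSFNMIFVAMLVGRQSCQVDICGCSEDMHHPISDGVSV
EYNIVVDGYGSQVNHVYCEKKDHYAFNGLWSSYQKAGADFEEVELEKVWYVDFAVWPTDG
TDDCQQNCYNGWHWCTGGDQDWISMHAKDSEQVLAFIQAHGINVIWTSWHGPVYDNHFDN
EIGPFVNTLAYRNYIHTGDIECIDFVTGYVTDIKHMHQEVPMGVEHFHPTSMHIIRTMQD
QPFEMLVMHKYVFLCTWFYENMMQQTEVDWPKFYPRNSLNEHHDNYPVREELQKGFVCPQ
TPDRRDLPRNPLTEESYIKAQVWTDYDPHKPSHDAYNIMRFDATCCLNRGDK
>Cglyc_7
INRHCQASDDHYERSGSCWTSMAQDRLWTLRCIFDVIDSACFPVKDARWMRWHEKKRFIY
RHEHLRTGFIGYMGMHRSELICKSFNMIFVAMPVGRQSCQVDIFGCLEDVHHPISDGVSV
EYNIVVHGLGSQVDHVYCENGDHYAFNGPWSRYQKAGQDREAVELEKVWYVDFAVWPTMG
TDDCQYPPYLGWHWCTGGDQDWTSMEAKDSEQVLAFVHFHGINVIWTSWHGPVYQNHFDN
EITPFVNTMAYRNYHHTGDIEIDDFVTPWVTDIKHMHQEFPMGVEHFHCASMHIIRYHQD
VPFEMLVHHKYVPLCQWFMENMMQQPEVDIPFFYPRNSLNEKHDNYTVREESQKGFVCSQ
TYDRRDLSDNPLTEESYILGQVWTDYDPHKPSPDRYNIRRFIATCHLNAGLL
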
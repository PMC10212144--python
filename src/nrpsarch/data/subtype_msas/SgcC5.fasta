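>SgcC5_0
VFNQMWRNVFMYAFLAEKVYSYAQTRLWTLFIYHMAGLAAETMQDAPAKIKCVPFEYIPN
RNSVVRTMFDISCKDHLVHHTLWWLGDFVMGLFGYTSIDVNCEEQCIVAMHHRISDGVSM
WRICWVGDTQDNNWPGISVHDAFQWTRKHLQNNWLVATMTSKHINDHRVYIDFAVWCDAQ
PVTAAMQKQKRNEKATMWKRSMLIMKEVPQWESMMVQPEQPYAIFNAIYTDMHCSYRQDE
HIGWFVNTLAPPNAIYDAAEFSWVTDPAETWAEKPCRITPNPTELWPFAAYQVQSARHQD
VPFEAEFEPAAECSVAWDMTAHQYTSWLVDYAVNLKHFFTTFEDRRFWDGMNKDHRSHWC
PTVERMKERNPLKDCMFVFKKSCRGDRCHKMEWGSEDWFLEMLTSMIGWKNC
>SgcC5_1
IFNQMWRNVFAYARSAEKVYSYAQTRLWTLFIYHQAGLCAETMQDAPAWIQCVPFEQIPN
RHKVLRTSFAINCKDHLVHHKLWWLTDFVPGLFNYTSLDVNCEQQCIVAMHHRISDGVSE
GRYCAKGMTDKNNWEGISVHDAFQWTRKHLRNNHLVPRMTSKHIYDHRVYPDFAVWCDAQ
PVTATMQLFKRNEKYTKQKRKMLIMKERPQWESMWVQFERPSAIKNAIHTDMHISYDQDE
HINWFVNTLAPRNAIYDNMEFSWVTDPAETWAEKPCRITPNPTELWPFAAYQVQSARFSD
VPAEAEFEPAAHCSVAGDRTLQQKTAWSVDYAVNLNHFFTTFEDRRAWWGMNIDHRSHWP
PTVERDKSRNPLQWCMFVFRKSCRFDQCHKMEEGSEDWFLEMLTSMIGWKYC
>SgcC5_2
IFNQMWRNVFMYLRLAEKVYSYAQTRLWTLFIEHQAGLCAETMQDIPAKIQCVPFEQIPN
RHEVLRTSFADSHIDHFVHHTLWWLGDFYGGLFGYTSLDVNCEEQCIVAMHHRISDGVSE
WRICAVGDTDKNYWEGISVHDAFQWTRKHLQNNHLVPTMTSKHINGHRVEPDFAVWCDAQ
SVTATMQKQKRNEKAKMWKRSMLIMKEVVQWESFGVQFEQPSAIKNAIYTDMHCSYDADE
HIGWMVNTLAPRNFIYDAMEFWWVTWGAETWAEKPCRITMNPTELWPFAAYQVQSARHQD
VPFEAEFEPAAECSVAWDETLQQKTAWLVDYAVNLNHFFTTFEDRRRWDGSNIDHRCHWP
PTVERDKSRNPLMDCMFVFKKSCRFDRRHKMEEGSEDWRLEMLTSMIGWMYC
>SgcC5_3
IFNQMWRNYFMYAALAEKAYSYAQPRLWTLFIEHQAGLCAETMQDAPAKIQCVPFEQIPN
RHEVLRTSFAISCMLVLVHHTLWWLGDRVIGLFGYTSVDVNCEEQCIVATHHRISDGVSE
WNICAVGDTDKNNWEGISVHDAFMWTRKHLQNNHLVPDMTSKHINDHRVYPLFAVWCDAN
PVTATMQKQKRNQKATMWKRSMLIIKEVPQWHSMMVQFEQPSAIKNAIYTDMHCSYDQDE
HIGWFVNTEAPRNAIYDAMEFSWVTDPAETWGEKPCRITPNPEELWPFAAYQVQSARHQD
VPFEAEDEPAAECSVAWFMTLQQKTARLVDYAVNLNHFFTTVEDRRYWDGMNIDHRSHWP
PTVCRHKSRNPLKDCMFVFKKSCRFNRCHKMEENSEDWFLEMLTSMIGWKYC
>SgcC5_4
IFNQMWRNSFDYARLAEKVKLYAQTRLWTLFIYHQAGLCAETMKDAPAKIQCVPFEFIPN
RHEVLRQSFAISCKCHYVHHTLWWLGDFVMGLFGYTSLDVTCENQCIIAMHHRISDGVQE
WRICKVGDTDKNEWEGISVHDMFQWTRKHLQTNHLVPTMTSDAINDHRVYPDFAVWCDAQ
PVTATMQKQKRNRKATMWKRSMLIMKGVPCWSSDMVQFEQPSAKKNAIYSDDVCSYTQDE
HIGWFVNTLAPRNAIYDAMEFSWVTDPAETQMEKPCRITPNPTELWPFAAYQVQSERHQD
VPFEAEWEPAAECSVAWDTTLQQKTAWLVDNAVNSHHFFTTCEDRRYWDGGNIDHRSHWP
PTVIRDKSRNPLKDCMFVFKKSCRFDRCHKMEEGSEQWFLEMLTSMIGWKTC
>SgcC5_5
IVNQNWMNVFMQARLAEKVYSYAQTRLMTLFIYHQAGLDAETMHDAPRKIQCVPFEQIPN
RHEVGRTSFAISCKDHLVHHTLWWLGDFVMGPFGYTSLYVNCLPQCIVAMHHRISDDVSE
HRICAVGDTDKNNWEGISFHDAFQWRRKCLQNNHLIVTMTSKHINDHRVYMDFAVWCDAQ
PVTATMGAQKRNERATMWKRSMLIMKEVPQWESMMVQREQPSAIKNAIYTDMHCSYDQEE
HIGWFVNLLAPRCAIYDAMEKSWVFDPAETWAEKPYCIGPNPTELWPFASYQVCSARHTG
VPFEAEFSPAAECSVAWDMTLQQKTAWLVDYEVNLNHHFTTFEDRRYWDGMNIDHRSHWP
PTVERSWSRNPSKDCMFVFKKSCRFDRCHKIEEGSERWFLEMLTMMIGGKYC
>SgcC5_6
IFNQMWRNVMMYARLAEKLYSSAQTRLWTLFIYHQAGLCAETMQDAPAKLQCVPFEQIPN
RHEVLRTSFAISCKRHLVHHFLWWLGDFVMGLFGYTSLDGNCEDQCIVAMHHRISDGVSE
WRICAVGDTDKRNWEGIAVHDAFQWTRKHLQNNHLVPTMTSKHDNDHRVYPDFAVWPDAQ
PRTATMQKHKRNEKATWWKRSMLISKERPQWESMMVQHEQPSAAKNAIYTDMHCSYDQDE
HIGWFVNTLAPRMAIYDAMEFCWVTDPAETWAEKPCRITPNPTELWPFAAYQNQSARHQD
VPFYAEFEPAAECSAAWDMTLQQKTGWLVDYAVNLNHFFTTPEDRRYWDGMNIDHRSHWP
PTVERDTSRNPLKFCMFVFKISCRFDMCHKMEPGSEDWFLEMLTSMIGWKYC
>SgcC5_7
MFNQDWRNCFMDAFLAEKVYSYAQTRLWTLFIYHQAGLCAETTQDACAKIQCVPFEQIPN
RHEVLRTSFAISCKDHLVHHTLWWLGDFVMGLFGYVSLDVNCEEQCIVAMHHRISDGVSE
WRICAVNDTDKNNHEGISVFDAFPMARKHLQNNHLVPTMTSKHINDERVYPDFAVWEDAQ
PVTATMQKQKLNEKATMWKRSMLIMKEVPQKESMMVQFEQPSAIKNAIYTDMHCSYDQPE
HIGWFFNTLAPRNAIYDAMWFSWVTDPAETWAEKNCRIAPNPTELWPFAAYQVQSANHQD
VPFEAEFEPAQEKSVSWDMTLQQKYAWLVSYAVNLNHFFTTFEDRRYWDGMNIDHRSHWP
PTVYRDKSRNPLKDCKFVFKKSCRFDRCHKMEEGSELWFLEQLTSMIGWKYC
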
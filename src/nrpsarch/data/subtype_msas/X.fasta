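>X_0
CTTRGFTVFQCHCHKFWWYGSDAQFRLWVLEKWKGCVTEKFPFTDLYNVGVAMSIYMYPN
RLEFLRTNFGVACQPPRKMVGCQMFMWSKYQITYEEQYSKCTYFNWCRIMPHAIVDGVSL
GAMGTVITNEESLDEEDRVIGTNLDYWNHYAQTDMPTKWACTNHQEWLHYNDFAVWMHNG
YIPAWPWEIAGEKLQWCLQSPASNVDSCGFTFQPRWMREMRDWKHSREMPNDCWGPMSFM
FIGAFQNTLALRYMAIQHLHRQDKIVNHSSTGRFNKWWFGLCPSNCAIRCHEDDKITHQA
LPCETEHFLRYIMNGQPRYQMQGLFWTMRDGKVEDHEAGVIVEVHKWYDQHLLYHHLIWP
NDFCRDMSRNPPICTHCPAVQVQPVNKEEDGNILSAMEDQASTRNRYEIHAQ
>X_1
CTTRQFTVFQCVCHVFWWYGSDAQFRLWYLEKWKGCVTEKFPFTDLYNVGVQMSNYMYGN
RHPDLRTNFGVACQPPTKMTLMQMFMWSCYQITYEAQYSKCTYFNLCNIMHHRISDGVSL
GAMGTMITNEESRDEEDRVIGTNLDYWNHYAATDMPQKWAQTNHQEWLHYNDFAVWMHNC
YIPAWPWEMGGEKVQWCLQSPAYNVDSCFKTFQPHWMREMRFWKHSTEMPNFCWGPMSFM
FIGAKYNTLWLRYMAIQMLHREDAIVNHSFTQPFNKWWFGTCPSNCAQRCYEDDTIRHHD
VPFETEHFLRYIMNGIIRYQMQGLFWTMRSGKVEDHEEGVIVEVHKWIDQHLLYHHLWGP
NDFWRDRSRNPCICTHCPAVQVQPGNCEEDGNILSAMEDQASTRCRYFIHAK
>X_2
CTDRQFTVFQCHCHVFWWYGSDAQFRLWYLEKEKGCVTEKFPFTDLYNVGNQMSGYMYCN
RHEDLRTNFGVACFRPTKMVGCQMFMWSCYQITYEEQYSKYTYFNLCNIMHHCISDGVSL
GAPGTVITNVGSRDNEDRVIGTNLDYWNHYAATDMPQKWAQTNHQEWLMYNDFAVVMHNC
PQPAWPWTIAVEKLHWCPQSPAYLVDSCFKTFQPRWMREMRFWKHSTEMPNDCWGPMTFM
FIGAFVNTLARRYMAIQQLHREDAIVNHSSTQRFNKWWFGTCPSNCAIRCHEDDTIRHQD
VPFEREHFLCYIMNGQPIYQMQGLFWTMRSGKVEDHEAGVIVEVLKWIDQHLLYHHLWWP
NLFCRDNSRNPLIPTHCPAVQVQPGHKREDGNILSAMEDQASTRCPYFIHAC
>X_3
CTTRPFTVFQCHCHVFWCYGSDAQFRLWYLEKWCGCVPEKFPDTDLYNVGVQMSVYMYGN
RHEDLRTNFGVACQPPTKMCGCQMFMVTCYQITYEEQYSKGTYFNLCNIMHHRISDGVSL
GWMGTVITNEESRDEEDRVIGTNLDYWNHYAATDMPQKWAQTNHQEWLPYNDFAVVMHNC
YIYAWPCEIAGEKLQWCLQSPAYNVDSCFKTFQPRWMREMRFWKHSTEMPNDWWGPMSFM
FIGAFTNTLALRYMAIQMLHREDAIVNHSSNQRFNKWWFGGCPSNCAIRKDEDDTIRHQD
VPFETEHFLRYIMNGQPRYQMIGLFWTMWSGKVEDHEAGVIVEIHKWIDQHLLYHHLWWP
NDLCRDMSRNPLICTHCPAVQVQPGNKEEDGNILSAMEDQASTRCRYFIHEQ
>X_4
CTTRQFTVFQCHCHYFWWYGSDAQFRLWYLEKWKGCVTEKFGFTDGYNEGVQMSVYMYGN
RHEDLRTNFGVAPQPPTKMVKCQMFMWSCYQITYEEQYSKCTIFNLCNIMHHRYSDGVSL
GIMGTVITNEESRDEEDRVIGTNCDYWNHYAATDMPQKWAQTNHQEWLVYNDFGGWMHNC
YIPAWVMEIAGEKLQWCLQSPAYNVDSCGKTFQKRWMRFNRFWKHSTEMPNDCWGPMSLM
PIGAFQNTLALRYMAIQMLHREDAIVNHWSTQAFNKWWFVTCPIRCAIRCHEDDTIRHQD
NPSETEHFLRYVMNAQPRYQMQGLFWTMRSGKVEDHEAGVIVLVHKFIDQHLLYHHLWWP
NDFCRDMSRNNLICTHCPAVQVQPENKEEDWNILSAQEDQASTRCRYFFHAQ
>X_5
CTTRYFTVFQCHCHVFWWYWSDAQFRLWYLEKWKGCVTEHFPFTDLVNVGVVMSVYGSGN
RHEDLRTNFGVACQPPTGMVGCQMFMWLCYQIRYEEQYSKCTYFNLCNIMHHRISDGVSL
GAMGTVITNEESRDEEDRPIGTFLDYWNHYAATDMPQKWAQTNHQAWLHYNDFAVWMHNL
YIPAWPWEIAGEKLFWCLQSPAYNVDSCFKTFQPRWMREMRFWKHYTEMPNDCWGPMSFM
FIGAFGNTLALRYMAIQMLHREDTIVNHSSTQRFNKWWFGTCQSNCAIRCHEDDTIRHQD
VPFETQHFLRYIMNGQPYYQMQGLFWTMRKGKSEDHEAGVIVEVHKWIDQHLLYHILAWP
NDFCRDTSRNPIICTHCPAVQVQPGNLEEDGNILKAMEDQAHTECRYFIHDQ
>X_6
CTTRQFTVFQFHCHVFWWQGSDAQFMLWYLEKIKGCVNEKFPFTDQYNVGFQMSVYMYGC
RHEDGRTNPGVACQPPTKMVGCQMFMWSCMQITYEEQYSKCTYFNLCNIMHRRISDGVSL
GAMGTVITNEESRREEDRVDGTNLDYWNHNAATDMTQSWAQTNHQEWLHYNDFAVWMHNC
YIPAWPWEIAGAKLQWCWQSPAYNVSSCFKTFQPWWMREMRFWKHSTEMPNDCWGPMSFM
FIGAFVNTLAVRYMAIQMLHREDAIVNHSSTQRFNKWWFGTCPSNCAIRCHEDKTIRHQD
KFFETEHFLRYIMNGQPRYQMQGMFCTMCSGKVEDHEAGCIVEVHKWIDQHLLYHHLWWP
NDFCRDMSRNPLICTHCPAVQVQPGNKEEDGNILSAMEDQASTSCRYFAHAQ
>X_7
CTTRQFTVFQCHCHVFWWYGYDAQFRYWYLEKWKGCVTEKFKFTDLYNVGVQMSVYMYGN
AHEDLRTNFGVAAWPPTKMVGCQMFMWSCYQITYEEQYSKCTYFNLCNIMHHRISDGVSL
GAMGTVITPEESRDENDRVIGWNPDYWNHYAATDMPQKWAQTNHQEWLHYNDFAVWMHPT
YIPAWPWEIAGEKLQWCLQSPAYNVDSCFKTFQPRWMREMRFWKHSTEMPNDCWGPMGFM
FIGAFVNTTALRYMAIDMLHREDAIVNHSSTQRFNNWWFGTCPSNCAIRCHEDDTIRTQD
VPFETEHFLRYIMYGQPRYQMQGLQWTMRSGKVEDHEAGVIVEVHKWIDQHLLYHHDWWP
NDLWRDMSRNPLICTHCPAVQVQPGNKEEGGNILSAMVDQASTRCRYFIHAQ
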
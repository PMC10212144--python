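>LCL_0
GRYMAAIIWWSVFAHRRSQLSNAQWRLWSLKDLWLVDFPGCQVIRQCDLSYNEMINRLEM
RHEFLRTRFQKIERVRHNMHRHTHCGSYENRLRPATSLREIGTSLCRQLMDHCISDGVSP
TGEEEETFFNLEEMPPFLNKVTLCMCRLCHMEGHTHISEWNVMLCEDWVYLDFAVWYQPF
MPQWLITDTDINAHHVIYTKTLGCVHRQMYWIIILDTAEQNDWYKRITNLKHSLGVWWKG
KIGDFVNTLAWRRERENCKIKNNYYMKPAGIYARMQDVQNQVVVTHIQFDFHCKKKTHQD
VPFESVRQMSVVKPQITAYCDINNIFNLCFHDHASNWHGINNWQRLFMPFSNNLTQTLQQ
GSTNRDWSRNPLCTFNCIWRRTIHAHCYWCGSRHYNWIKGYAREQAKAQYNP
>LCL_1
GRYMAACIWWSVFYCRRLQLSNAQQRLWSLKDLWQVDFCGCQVIRQCNLSYNEMMNRLEY
RHEFLRTRFQKIERVYRNMHRHTHMDPPENRLRPATSLMHIGTSLCRQLAHHCISDGVSP
TGEEEETFFSTEEMPPFLNKVTLCLCPICHLEGLTHISEWNKMLCEDSVYLDRAVWYQPF
MPQWLITDTDINAFHVIYTKTLGIVHRQYYWINILMTATQHDWYKRSTNLKHSNGVWRFG
KIGDDVNTLAWRRESENCKIKNNNYTMPAGIYARRQVTQNQVVVTMVQFMFHCKQKTHQD
VPFESSRQMSVVKPQIPAYCDINVIFNLCFHIHASNWHGINNWWRLFMVNSNNLTYTLQQ
GSTNRDWSRNPLCTFNDIWRRTIHAHCYWCGSRHYNWIKGQAREQAKWQYMP
>LCL_2
GRYMAACIWWTVFACRRLQKSNAQQVLWSFKDLWLVDFCGCQVISQCNLSYNEMMNRLEM
RHEFLRTRFQKIERVRRNMHRHTHMGPYEYRHRPATSLMCMGTSLCRGWMHHCISDGVRP
TGEEEETFFVTEEMPPFLNKVTLCMCRERHMEGFTHPHEWNKMLCECSVYLDFAVWYQPF
MPQWLITDSDRNAHHVIYTKALGIRHRQTYWIIILDTAEQNDWYKRITILKHSNGVWWFY
KIWDFVNTQAWCRESENCKIKSNNYRKPALIYALRQDTQNQVVVTHIQFMFHCVKKTCQD
VFFESSRQMSVVKPQITAYCDNNNIFNLDFHLHASNWHLINNWCRLIMPNSNNLTHILQQ
GSDNRDWSRNPLCTMNCIWRRTIHAHCYGCGSRHYNWIKGYAREQAKAQYNP
>LCL_3
GRYMAACIWWSVFACRRGQLSNAQQYLWSLKDLWLVDFCGNQVIRQCNLSYNECMNRLEM
RHEFLRTRFQKIERVRRNMHRHTHMGPYENRLRPATSLMEIGTSLCRQLWHHCIVDGVSP
TGEEAETVFSTCRMPPFFNKVTLCMCCECHMEGHMRISEWNKMLCEDSVYLLFAVWYQPF
MPQWLITDTDINAHHVIYTKTLGIVHRQMYWIIILDTAEQNDWYKRITNLKHSNGVWLFG
KIGDFVNTLAWRRESENCKIKNNNYTKPAGIYARRYDTKNQVVVTHIQFMFHCKKWTHQD
HMFESSRQMSVVKPMITAWCDINEIFNLCFHIHASNWHGINNWQRTKMPNSNNLTQTLQQ
IPTNRDWSRNPLCTFTCIARRTIHAHCYWCGSRHYNAIKGYAREQAKAQYNP
>LCL_4
GRYMAACIWWSVFDCRRLPLSNAAQRLWSLKDLILVDMCGCQVIRQCNLSYNEMSNRLWM
NHEFLRTRFQKKERVRRNMHRHTHMGPYENRYRPATSLMEIVTSLCRQAMHHCISDGVSP
TGEEEETFFSTELMPPCLNKVTLCMCRECHMEGHTHISEWNKMLCEDSVYLDFAVWYQRF
MPQWLITDTDINIHHVIYTKTLGIVHRQMYWIIIWDTKEQNDWYKRITNLKHSNGVWWFG
KIGDFVNTLQWRRESELCKIKNNPYTAPAGIYARMQHTQNQVVPTHIQFMFHCKKKTHQD
VPFESSRQMSMVKFTITAYCDINNIFQLFMHIHCSNWHGINTFQRLFMPNNNNLTQTLQQ
GSCNRDWSRNPLCTFNCIWRRTIHAHCYWCGSRHYNWIKGTAREQADAQYNP
>LCL_5
GRYMAACIWWSVFQCLRLQLSNAQQRLWSLKDLWLVDFCGCQVDRQWNLSYNWMMSTLEM
RHEFLRTRFEKIERVRRNMHRHTFMVPYENRLRPATSLMEIGTSLCRQLMSHCISDGVSP
TGEEMETFFSTEEMCPFLNKVTLCMCRECHMEGHTHISEWNKMLCEDSVYLDFAVWYQPF
MPQWLITDTDINAPHEIYTKTLGIVHRQMYWIIILDTAEQNDWYKRICNLKHSNGVWWFG
KIGDPVNTLNPRRESENCKIKNNNYTKPAGIYARRQPTQNNVVVTHIQFMFHCKKKTHQD
VPFGSSRQMSVVKPQITAYCDINNIFNLCFHIHAMNWHGINNWQQLFMPHENNLTQTLQQ
GSTNRDISRNPLCWFNCIWRRTIHAHCYHCGSRHYNWIKGKAREQKKAQYKP
>LCL_6
GRYMAACIWWSVFACRRLQLSNAQQWLWSLKDLWLVDFCGCQVIHQCNLSYCEMMNRMEM
RHEFLRTRWQKIERVRRNMHRHTHMGPYENRLAPATSLMEIGTILCRQLMHHCISGGVSP
TGEENETYFSTTEMPPFLNKVTLCMCRECHMEWHTHISEWNKMLCEDSVYLDFAVWYQPF
MPQWLITDTDINAHHVIYTKTLGIVHRQMYWIIILDTAEQNTWYKRITNLKHSNGVWWFG
KIGDFVNTLAWRRESQNCKIKNNNYTKPAGIYARRQDTQNQVVVTHIQFMFHCKKKTHQD
VPFESSRQMSVVKPQIEAYCDINNIFNLCFVIHASNWHGINNWQREFMPNSNNLTQTLQQ
GSTNRDWSRNDLCTINKIWRRTLHAVCGWCGSRHYNWIKGYAREQAKAQYNP
>LCL_7
GRYMAACIWWSVFACRRLQLSNAQQRLWSLKRLWLVDFCGCQVIRQCNLSYNEMMNRLEG
RHEFLRTRFQKIERVRCNMHRHTHMGPYENPLRPATSLNEIGTSLCRQLMHHCISDGVSP
TGEEEETFFSTEEMPPFLNKVTLCMCREWHMEGHTHISEWNKMLCENSVYLDFAVWYQPQ
MPQWLITDTDINAHHVIYTKTLYIVHRQMYWIFILDTAEQNDWYKRITNLSYSNGVWDFW
KIGDFVNTLTWRRESENCKIKCNNYTKPAGIYARRQETQNQVVVTHIQFMFHCKKKTHQD
VPFESSRQMSVVKPQITAYCDINNIFNLCFHIHADPWHGINNLQRLFMPNSNNLRQTLQQ
GSRNEDWCRNPLETFNCIWRRTIHAHCYWCGSRHYNWIKGYAREQAKAQYNP
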
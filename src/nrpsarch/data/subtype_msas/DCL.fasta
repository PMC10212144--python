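>DCL_0
GVNHCRGRMSVRKPESVGFYSIAQGRLWTLMIEWHYPASYDEGFALFNGPLFDDGEREMM
RHEYLRTTFWDDFDPLPGISKAGCYSSDQPDVPGETIDMEHNCPISWCFMHHSISDGVSY
LWMFWRKEFEMKSCFHDIHMTPRYEILIFYEYMNARVDHFNTGIKPCQEYDWFAVWDRLD
IDYDAMEGYSTHSVRHWNETWHHKFLPMFCWQSHMIHMGEPHHKEVWAVWWYFSNHWPGN
VIGDFVMTLAWRQAQAQIYGPKTYDRTLTRNKFCTVGMKKDWAGHCLFQARPVFVKSHQD
VPFETKKGPPPMPCWHIQFVPHCPQELRRDITTKSRTGDYPNLQFKPGWTDQGVYRGRCR
GKVARDTSRKDLWDYKRALHPCFPVAATLLCWGMWHNWTLRCKHDDKEVHRQ
>DCL_1
GVNHPRGRISVRKPESVGFYSIGQGRLWTLMIEWHYPASYDEGLALFWGPCFDDGEREMM
RHMDLRTTFWDDFRPLPGISKAGIYSSDQPDVHSETIDMEHNAPISWYFMHHSISDGVSY
LWMFWRKFFEMKSCFHAIHMTPRYEILIFYTYMNARVCHFNTGIKYCQEYQDFAVNDRLD
IDYDAMEGFGTHSVRHWHETHHHKFLPMFCWQSHMIHMEEPHHKEVWAVWWYFENGWPGN
VIGDFVNFLAYRQAQAQIYGPKTFDTTLTGNKFCTCGMKKDWAGHFLFQARPFFVKSHQD
QTFSTKKGPPPMPCWHIQFVPFCPQELRRDITTKMRTGDYPNLQFKPGWTDQGVYVWRCR
GKVDRDLSRNPLWDKKIALHGCFPETATLPCWGMWHNWTLRMKHDDKEVHWQ
>DCL_2
GVNAWTGRYSVRKEESVGEYSIAQGRLWTLMIEWHYPASYDEGFALFWGPCKDDGEREMT
RHEYLRTTAWDDFRPLPGISKAGCYSMDQPDVPSETIDMHHNAPISWCFMHHSISGGVSY
HWDFWRYEFEMKSCFHDIHMTPRYEILIEYHYMNARKCHFNTGIMYCQEYDDFAVWDELD
IDYDAMEHYSTHSVRHWHETHHHKFLPMFCWQSHMIHMGEPPHKEVWAVWWYFSNHWPGN
VIGDFVNTLAYRQAQAQFYGSKTFDTTLTRCKFCTVGMKKDWAGHCLFQARPFFVKSHQY
VPFETKKGPPPMPCWCIQFVPHCPQELRYDITTKHRTGDYPNLQFKPGWTMQGVERGRCA
GKVARDLSRDPLSDKHRALHGCFPITKTLPCWGMWHNWTLRCCHDDKEVHRQ
>DCL_3
GVNHTRGRMVVRKPESVGFYSIAQGRLWTLMAEWHYPASYDEHFALFWGPWFDDLEREMI
RHEYLLTCFWDDFRHLPIHSKAGCYSHDQTDMPSETIDMEHNFNISWCFMHHMIADGVSY
EWMFWFKRFEMKSCFHDIHMTPRYEIWKFYTYMNARVTHFNTGIKYCQEYDDFGVWDRLH
IDYDAMEGYSTHSVKHWHETHLHKFLPMFCWQSHMIHMGEPHKKEVWANWWYFSNYWPGN
VIGDFVNTLAYRQAQAQICGPKTFDTTLTRWKFCTVGMKKDWAGHCLFQARPFFVKSHQD
VPFETKKGPPPMPCWHIQFAPHCPDELRRDITTCMRTGDYPHLQFKPGWTDQGVYRGRCR
GKVASDLSRNPLWDKKRALHECRPITATLPCWGMWHNWTLRCKHDAKLFHMQ
>DCL_4
GVNHPRGRMSVRKPESSGFYSIYQERLWTLMIEWHYCASYDEGFALFWGPCFDDGEAEMM
SHEYLWTTFWDDFRPLPGISKAGCYSSDQPDVPSETIDMEHNSPLSWCFMHHTISPGKSY
LWMRWRKEFEMKSRFHDIHMTARVEILIFYTYMNARVDHFNTGIKYCQEYDDFAVWDRLD
IDYDAMEGYSTHSLRHWHETHHHKYLPMFCWQSHMIHMMEPHHKLVWAVWWYFSNHWPGN
VIGDFVNTLAYRQAQAQIYGPKTFDTTLTRNKFCTVGMKKDWAGHCLFQARMFFVKSHQD
VPFETKKGPPPMFCWHIQFVPHCPQELRRDIMTKMRTGDYPNLQFAPGWTDQGVYRGRCR
GQVARDLSRNPLWDKKRALHGCFPITATLDFWGMWHNWTLRCKHDDKEVAPQ
>DCL_5
GVNHHRGRMSVRKPESVGFYSMAQGRLWTLMIEWHYPASYWRGFYLFWGPCFDDGEREMM
RHMYLRKTFWWDFRPLPGISKAGCYSSDQPYVPSETEDMECNAPISWCWMHHEFSDGVSY
LWMFWRKEFEMKSCFHDIHMFPRYEILIFYTYMNIRVCHPNTDIKYCQEYDDFAVWDRLD
ILYDAMEGYSTHSVRPWHETHHHKFLPMFCWQSHMIHMGEPHHIEVWAVWWYFSNHGPGN
VIGDFVNTLAYRQAQAQIYGPKTFDTTLTRNKFCTVGMKKKWAGHCLFHARPNFVKDHQD
VPFETKKGPPPMPCWHLQFVPHCPQELRRDITTKVHTGDYPNLQFKPFNGDQGVYRGRCR
MKVAIDLSRNPLWDKKRALHGYFPITATLPNWGMWHNWTLRCKHDDNEVHRK
>DCL_6
GVNHPDGRASIRKPEQVGFYSIAQGRLWTLMIEWHYPACYDEGFALFWGPCWDDGEREMV
RHEYLWTTFWDDFRPLPGISKAGCYSSDQPDVPSETIDMHHNAPISWCFMHHSISDGVSY
LWMFWRVEFEWKSCFHDIHMGPRYEILIFYTYMNARVCQFNTGLKYCQEYDDFAVWDRLD
IDYDAMEGYSTHSVRHWLETHHHKFLPMFCWQSHMIHMGWPHHKEVWAVWWYFSNHWPLN
VIGDFVNTLAYRQAQANEYGPKHFDITLTRNKFCTVGMKKDWAGHCLFQAQDFFVKSHQD
KPFETKKGPPPMPCEHIQFVPHCPQELRRDITTKMRTGDYPNLQFKPGRTDQGVYRGRCR
GKQARDLSRNPLWDKKRALHGCFPITATLPCWGMWHNWTLRCKHDDKEVHRW
>DCL_7
GVFHPRGRMSVRKPESVGFKSIQQGRFWTLMITWHYPASYDEGTALFWLPCFDDGEREMM
RHEYLRTTFWEDFRPLPGISKAGCYSSDQPDVPSHTIDMEHNAPISWCFMHHSISDGVSY
LWMFWRFEFEMKSCFHDIHMDPRYEILIFYTYMEAGVCHFNTPIKYCQEYDDFAVKDRLA
IQYVAMEGGSTHSVRHWHETHHHKFGPMFCWQSHMIHMGEPHHKEVWAVWWYFSNHWPGN
VIGDFVNTLAYRQAQAQIYGPMTFDTTLTRNKFCPVGMKKDWAGHCLSQLRPFFFKSHQD
VPFETKKGGPPMPCWHIQFHPHCPQELREDITTKMRTGDYPNLQFRPGWTDQGVYRGRCR
GKRARDLSRNPLWDKKRQLHTCFPITATLPCWGMWHNWTLRCKHDDKEVHRQ
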
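>Starter_0
CDPWIITYSYWAHWSSIYVKSAAQDRLWGLTPWIREMEIHLNWEFGYDYLMGQPFFGDNF
RHETIRTHFYYDGIWCHTTHSDLRTERICTIHQWGKMIPMRWDETCARWMHHYISDGVSA
RMWIVIEPQCWKKSCEGVPPVGGEYYVDCQPKGKGHHYLQHNMRWSRMSNFDFQVWMFMV
VLILAWCGPYCQLDKWCWFRLAAPQWGVHCKQDGEMPGCVELGYRSFHAIKRYAWTPFQR
PWVYFVNTLATRMPSMHLVRFMLCDVEFEVRYMLGVVQFYLVIMLPLNKLIDIPGDSAQD
VLKEMRKPPGQNQPWGHLVVRRNAAQMAIDQWNIGWRSAHTFSALFGKPIPCGCMTWALQ
RGRVRDQSRNPLPEQDPDMIMTRHIDILLDEQPLHGIRQMKAQTNFHQVALR
>Starter_1
CTPFIITYSYVAHWSSIYVKSAAQDRLGGLTPWIREMEIHLNEEFGYDDLMGQPFFGDPF
RHETLRTHFYYDGIWCHTTHSDLPTERICTITSWGKMIPMRWIETCNQWLHHYISDGVST
RKWIVIEPACKKKSCEGSQPVGGEYYVDCQPQGKGHHYLQHNMRWKRMRYFDFAVWQHMW
VLILAWCEPYNQWDKWCWFRLAALGWGVHCKQDGEMPGCVELGYRSKHAIKDYAWTYFQR
PIGYFVNTVATRMPSMHLVKFMLCQVEFEVRYMLGVVMWYQVILLMLNKLIDWPGDSHQD
VMFEMRKPPGSNCPWGHLVVRRIAAQMIIDQANIGWQSAATFSWLFGKPIPCGCMTWALQ
RGRCRSQSRKPLPIHDPLLRMTRHIDILLDPLPNYGIRQMYAQFYFHQVALR
>Starter_2
CTPNIHTYSYWAHWPSIYVTSAAQDRLWGLTPWIREMEIHLNEEFGYDDLMNCPRFGDPQ
RHWLLRTHFYYDGIWCHTTHSDLRTERICTIHHWEKMIPMRWIETCNQFMHHYISDGVSA
RKWIVIEPVCKKKSCEGVPPGGIEYYVDCQPQGKGHHYLQHNMRWSKHRYFDFAVWQHMV
VLILAWCEPYPQWDKWCWHRRAALGWGVHCKQDGEMPGCVELGYRSFHAIKDYAWTYFQR
PIGYFVNTSATRMPSMHLVRFMLCDVEFEVMYMLGVVQWYQVILLMAHKLIDWPGESFQD
VPFCMRKPPLINQPWGHLVVRRLAAQMGNDQWNIGWQSAATFSAPFGKPIPCGCMTVALQ
RGRVRDQSGNPLPEQDYLLRMMRHIDILLDPLGNHGIREMYAQIYFAQVALR
>Starter_3
CEPHIITYSYWAHWSSIIVASAEQDRLWGLTPWIREMEIHLNEEFGYFDLMGQPFFGDPF
RNETLRTHFYYDGIWCHTTHSDLRTERICTIHSWGFYIPMRWIESCNQWMHHYISDGVSA
RKWIVIEPVCKKKSCEGVQPVGGNYYVDCVPQGKGHHYLQHNMRWKRMSYFDFAVWQHMV
VLILAWFEPYCQWDKWCWFRLAALGWGVHCKQDGEMVGCVELGQRSFHAIKDYAWFEFQR
ALGYFVNTLATRMPSMHLVTFMLCDVEFEVRYMLFVVQWYQVILLMLNKLIDWPGDSHQD
VPFEMRKPPGMNQPWGHLVVRRIAAQMGLEDWNIGSQSAATFSAVFGKPIPCGCMTWALQ
RGRVRDQSRNPLNEQDPLLRMTAHIDILLDPLPNHGIRQMYADTYFHQVALR
>Starter_4
CTPHIITYSYWAHWSSIYVKSAAQDRLWGLTPWIAEMEIHLNEEFGYDDLMGQPFFGDPF
IHVTLQTHFYYDGIWCHTTHSDLRTERICTIHSWGKMIPMRWIETCVQWMHHYISDGVSA
RKWIVIEPVCKKKSCEGVPPVGGEYYVDCQPQGKSHHYLQHNNRWNRMSYEDFAVWQHMV
VNNLAWCEPYCQWDKWCWFRLAALGGGVHCKQVGEMPGCVELGYRSFHAIKDYVWTYFQR
WIGNFVNTLATRMPSMHLVRFMLCDVEFEVRYMHGVVQWYQVHLLMLGKLIDWPGDSHKD
VVFEMRKPPGINQPWGGLVVQRIAMQMGIDQSNIGWQSAATFSALFWKPGPCGCMTWALQ
RGRHRDQSRIGLPEQDPLLRMTRHIDIVLDPLPNHGIRQMYAQTWFHQVALR
>Starter_5
VTPHIITSSYWAHIQSINVKSAAQDRLWYLTCWIREMEIHLNEEFGYDDLMGQPFGGDPF
RHETLRTHFYYDGIWCFTTMSMLRTERICTIHSWGGMDPMRWIFTCFQWMHHYWSDGVSA
RKWIVIEPVCKKKSCEGVPPVGGEYYVDCQPQGKGHHYLQHAGRWKRMSYFDFAQWQHMV
VLILAWNEPYCQLDKPSWFRLAALGWHVHCKQDGSMPGCVELGYRSFHIIKDYAWTYFQR
PIGYFVNTLATRMPSMHLVRFMLCDVEFEVRYMLGVVQWYQVILLMLNKLIDWPGDSHQD
VPFEMRKPPGINQPRGHLVVRRIAAQMGIDQWNIGWQSAAAFSALFGKPIPCGCMTWALQ
QGRVRDQSRNVLPEQDPLLRMTRHIDILLCPLPNHGIRQMYAQTYFHQVALR
>Starter_6
CTPHIITASYWAHWSSIYVKQAAQDRLWGLTPWIREMEIHLNEEFGYDDLMPQFFFGDPF
RHMTGRTHFYYDGIWCHTTHSMLDTERICTIHSWGKMIPMRWIETCNQWHYHYISDGVSA
RKWIVIEPVEKKKSCEGVPPVGGNYYVDCQPQILGHHKLQTNMRWKRMSYFDFAVEQHMV
VLIIAWCEPYCQWDKWCWFRLAALGWGVHCNQDGSMPGNVELGYRSFHAIMDYAWTYFQR
PIGYFVNTLATRMPSMHLVRFELIDVESEVRYELGVFQWYQVIYLMLNKFIDWPGDSHQD
VPFEMRNPPGINQPWGHLVVRRIAAQNGISQWNIGWQSAATFSALFGKPIPCGCMTWALQ
RGRVRDQSRNPLPEQIPLGRMYRHIDILLDPLPNHGIRQMYAFTYFHMVGLR
>Starter_7
HTRHIITLSYWAHWSSIYVKSAAQDRLWGLTPWYREMEIHKNEEFGYLDLMGQPFDGDPF
RHETLRAHFYYDGIWCHTMHSDLRTERICTIHSWGKMVPIRWIETCNQWMHHYISDGVSA
RKWIVIEPVCKKSSCEGVPPVGGEYYVDCQPQGKGHHYLQHNMRWKRMSYFDFAVWQHMV
VLILAWCEPYCQWDKWCWFRLDALGWGVHCKHDGEMPGDVELKYHSFHAIVDYAWTYFQR
PIGYFVNTLATSPPSMHLVRLMLCDVEFNVRYMLGVVQWYQVILKMLNKLLDWPGDSHQD
VPFEMRKPPGINQPWGHLVVRRIAAQMGIDQWNIGWQSNATFSALFGKPIPCGCMTWALQ
RGKHRDQSRNPLPEQDPLLSMKRHIDILLDHLPNTGIRQMYACTYFHQVALR
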
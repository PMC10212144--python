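>Cyc_0
IPYFLMQGDRGDFSVVWFTSSYAQIRLWLLKDPTCWPGMVAIIRPKWLWHNKIAPQWCWN
RHESLRTHFKYPPCPVKMSDKMWNHCSKFQMFVFQFQIFENWPCHEVIIDWSMQDGDSCN
AECMFHMFKAWELTESTVRITWLGMHWMEGHASEPEDGQEPQKQSFKDEYYDFAVWQFWR
GFNHLHSDYGFLRLRYGNCLHNVDYISLRLMMGTHMFPTTTYHRVWEFSNATRCRGETLW
HIGWFVNTLACRCFVIKQDSWWMAHAPRWTGCIFMAPYEYFYAIAAPTYRASWYTDIHQD
VPFEQCPAGDQASEAHMMGRRPVERMDWLLVQHPLEKRNMRMAPYYCIRSTYEGIESFNM
RCQIRDGSANPLYGKFDAIFDAEIHITNPAIPYMELTGENHLAYRHNPKEMV
>Cyc_1
IPYFLMIGDRGKHSVMWFTSSYAQIRLWLFKDPTCWPGMVAIIRPKWLWRNKIAPQWCWN
RHESLRTNDKYPPCPVKMSDKMSNHYSKFQMFVMQFQIFENWPCHEVVYDTSTQDGDSCN
AECMQHMFKAWELTESTVRITWLGMHKMEGHCYEPWDGQAPQKQSFDQEYYDFAVWQFWR
GFNHLHSCYGFLRLRYGNCLHNVDYISLEEMMITHMFPTGHHDRVQEFSNMTWCYGETLW
KIGLFVNTLAARLEVIKQDSWWGAHAPRPVGCIFIAPYEWFYAIAAPTYRASWYTDIHQD
VPFEQCPAGDTASEWHCNGRDPVERMDDLLVCHKLEKRNMRMANARCIRSTYEGIESFNM
RCQIRDGSRNPLRRKFDAIFDAEIHITNPAIWYMELTGEHHMVYRHIPKEVV
>Cyc_2
IPYFLMQGDRGKFSVMLFTSSYAYIRLWLLKWPRCWPEMVAIWRPKWLWHNKIAPQWCWN
RNESRRTNFKYPPRPVKMSNKPCNHCSKFQMFKFRFQIFENWPCHEVIIDTSQQDGDSCN
AECMQHMFKAWELTESDVRLTWLGMHKMEGHAYEPPDGQANQKQSFDQELKDFAVWQFWR
GFNHLHSDYGFLRLRYGNCLHNVDTISLELMMITHMFPTGFHARVWEFSNATRCRGETLW
KIGWFVNTLAAQCFVIKQDSWWGAHAPRWPGCIFMAPYEWFYQIANPTYWASWYTDIHQC
VPFEQCPAGDTVSEAHCNGLDPVERMDWLLVCHKLEKRNMRMANAYCICSTPEGEESFNM
RCQIRDGSINPLRGKFDAIFDAEIHITPPAIWYMELTGMHHLAYRHIPKEVV
>Cyc_3
IPYFLMQGDRQKFAVMWFTSTYAQIRLQLLKDTTCWPGMVAIIHPKWLWHNKIAPMWCWN
RHESLRTNFKYPPCPVKMSAKMTNHCSKFQMFVFQFEIFENWPCHEVIIDTSDQDGDSCN
AECMQMMFKVWELTESLVRITWLGMHKMEGHAYEPPDGQAPQKQSFDQEYYDWAVQQFWR
GFNHLHSDIGFLRLRYGNCLHNVDYISLELMMITHMFPTGHPAGVWPFSNATRCRGETLW
KIGWFVITLAARCFVIKQDSWCGAHAPAWTGCIFMAPYEWFYAIAAPTYRASWYTDIHQD
VPFEQCPAGDYAAEAHCNGRDPVERMDWLLVCHKLEKRNMRMANAYDIRSTYEGIESFNM
RCQIRDGSRNPLRGKFDAIFQAEIHIRNPAIWYMELTGEHHLAYRHIPKEVV
>Cyc_4
IPYFLMQGDRGKFSVMWFTSSRAQIRLWDLKDETCWPGMVAISRPKPLFHNKIAPQWCWN
RHESLRTNFKYPPCPRKMSDMMTNHPSKFQAFVCQFQIFENCSCHEVIIDTSDQDGDSCN
AECMPHMFKALELQESTVRITWLPMHKMLGHAYEPPDGQAPEKQSFDQEYYDFAVWQFWR
GFNHLHSDYGFLRLRYGNCLHNVDYISLELMMITIMFPTQHHAQVWEFSNATRCRGETLW
KIGWFVNTLAARCCVIKQDSWWHAHAPRWTGCIFMAPYEWFYAGAAPTYRYSEYTDIHQH
VPNEQCPAGDTALNAYRNGRDPVERMDWLLVCHVLEKRNMRMAEAYCIRSTYEGIEMFNM
RCQIRDGSRNPLRGKFDAIFDAEIHITEPAIWYMELTGELHLAYRHIPKEVV
>Cyc_5
IPYFLMQGDRGKFSVMWFTSSYAQIRLWLLKDPTCWPGMVAIIWYKWLWNNWIAPQWCWN
RHESLRTNFKYCPCPVKMVAKMTNHCSKFQMFVFQFQIFENWPCHCVIIDTSDQDGDSCN
AEPMQHMFWAWELTESTVRITWHCMHKMEGHAYEPPDGQAPQKQSFDQIYYDMAVWQFWR
GFNHLHSDYGFLRSRYGNHLHNVDYISLELMMITHMGPTGEHARVWEFSNACRCRGETLW
KEEWFVNTLFARCFVIKQDSWWGAHAPRWTGCIFMLPYEWFYAIEAPTYFASWYTDIHQD
VPFEQNPAGDTASEAHCNGRDPVERMDWLLVCHKLEKRNMRMANAYCIRSTYEGRESFNM
RCQIRDGSRNPLRWKFDAIFDAEIHNTNPFIWYMELTGEHHLAYRHIPKEVV
>Cyc_6
ISYFLMQGDRGKFHVMWFTSKYAQHRLDLLKDPTCWPGMVAIIRPKWLWHNKIAPGWCWN
RHESLRTNNKYPPCPVKAQDKMTNICSKFQMFVFQFQIFENWPCHEVIIDTSDQDGDSCG
AEWMQHMFKAWELTESTVRITWLQMHKMWGHAYEPPDGQPPQKQSWDQEYYDFAVWQFWR
GFNHLHHDYGFLRLRYGNCLHNVDYISLELMMITHMFPTGHHAYVWEFSNAYRCRGEYLW
KIGWFVNTLAARCGVIKQDSDWNAHAPRWTGCIFMAPYCWFYKIAAPTYRASWTTDIHQD
MPMEQCPAGDTASEGHINGRDPVMRMDWLLVCHKLEPRNMRMANAYCIRFTYEGIESSNM
RCQIRDGSRNPLRGKFDAWFDAEIVITNPAIWYMELTVEHHLAYRHIPKEVV
>Cyc_7
IPYFLMQGDRGKFSVMWFTSSYAQNRLWLLKDPTTWPGMVAIIRCKWLWHNKIAPQWDWN
RHESLRTNFKYPPTPVKMSDKMTNHCSKFQMFVFQFQIFENWPCHEVIIDTSVQDGDSCN
HECMQHMFKAWELTESTVRNTWLGMHKMEDHAYEKPDGQAPQKQSFDQEYYAFAVWQFWR
GFNHLHSDYGFLRLAYGNCLGNVDYISLELMMITHMFPTGHHARVWEFSNATRCRGETLW
KIGWFVNTLAAMCFVIKQDSWWGAHAPRWTGCIFMAPYEWFYAIAAPTYRASWYTDIHQD
VPFEQCAAGDTAEEAHCNGRDPVERMDWLLVCHKLEKPNDRYTNAYDIRVTYEGIESFNM
RCQIRDTRMNPLRGKFDAIFDAEGHITNPMIWYMCLTSEHHLAYRHIPKEVV
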
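>I_0
WKMVVYEWISGGIYNPNILHSFAQRRLWSLHEDLYMLMYITKVHMMQFEKQGTGCFLGKA
RHVVLHTFFRWDPSDKPCGFMVPTGHQHFHLIPCKSTGMEVWWWEPVWLMHHLISDGVSV
RCIHCGHNMIGYEFDIDIVFLLANYWSSWGSWTHATRGSTWSAPFPMDDYEDFAVWPLNT
LEAYYFASACPGQMSTPWGMQQKQSKQYMRINMCALAVANWAASCPCKHSCCNFRIDPCS
GIGTFVNTFASRGCWEESPHDAVQSILQRDLWRYNMHFRSKPVSYSFCRQVFWESKEHQD
VPFMHFTRLQFFRRWNEWASDWGHYVPMERTDKAIPEACTNKRVNWHWPDTPYNWMRDSG
GMVRRDSSRNPLKKRHYISWQNHSCAHDFNRMSTLVWRTPCWSPLMGSPGNY
>I_1
IKGVVYEWISGGIYNPNQLHVFAQRRLWVLHEILYMLMYPTKFHQMQFEKQGTGCDPGKW
RHESPRTFPRWTPSKKPCLFMVPTGHQHFHLIPCKSTGLEVWWWSPPALMHHLISDGVSW
RCIHCHHNMIGYEFDIDIVFLLANYWSSWGSWTHAERGSTWCAPFYMDDGELFAVGPLNT
LEAYYFASHCPGQMSTPKGMVQKQSKQYERINRFALAVANWAASSPCKHGCCNDRADPCS
GIGTFVNTLASRGSWEESPHDAVQSIKQRDLNQYNHHFRSKPVEYSMQRVVFWESKEEQD
VPFEHFTDLQFFRRWNEWASDWGHHVPGERQGKVIPTACTNKRVNWHWPDTPVNWMRDSG
GMVRRDSSRNPLDKRHYISWQNHSCAHPFNRMSTLEWTTWCWSPLMGSPGNY
>I_2
WKMVVYEWISGGTYNPNQLHSFAQRRLWVNHEDLYMLMYITKVHEMQFEKQGTGCDLGKW
RHEVLRTFFRPCPSKKPCGFMVPAGHQHFHLIPCKSTGMEVWWWEPFWLMHHLWSDGVSV
RCIHCHHNMHGYEFDIDIVFLLANFWSSWGKWTHAERGSTWSTEFYMDDVEDFAVWPLNT
LEAYYFASACPGQMSTPQGMVQKQSKQYMNINRCALAVANWAAQSKCKHSCCNFRADPCS
GIGTFVNTLASRGCWEESPHDAVQSIKQRDLNDYNMHHRSKPVSYSFCRVVFWESKQHQP
VPFEHFTDLQFFRRWNERASDWGHHVPMEAQDWVIPHACTNKRVNWHWPGTPYNWMRDSG
GMVRADSSHNPLDKWHYISWQNHSCAHDFNRHSTLVWTTACGSPLMTSPGNY
>I_3
WKMVVYEWISGFIYNPNQNHSFAQRRLWVLHHDLYMLMYITKVHFMQFEWQGTGCDLGDL
RHEVLRTFFRWTPSKKPCGFMVPTGHQHFHLIPDKSTGYEVWVWEPFALMHHHIIYGVSV
RCIHCHHNEIGYEFDIDIVFLLANYWLSWGSLTHAERGSTWSAPFYMDDYEDFAVWPLNS
LEAYYFAIACPGQMSTLKGMGQKQWKQYMRINRCALAVANWAASSPCKHSCCFFRADPCS
GIGTEVNTLASRGCWEESPHDAVQSIKHRDLNRYNMHFRSKPGSYSFCRVVFWESKEHQD
VPFEHFTHLQFFRAWNEWASDFGHHVPMERQDKVSVEACTNKYVNWHWPDTPYNWMRDSG
GMVRRDSSRNPLDKRHMISWWAWSCAHDFNRMSTLVWTTPCWSPLMGSPMNY
>I_4
WKMVVYENISGGIYNPNQLHSFAQRPLWVKHEKLYCLSYITKVHQMQFEFQGTGCDLDKW
RHEVLRTFFMWTPSKKPCGIEVPTGHQHFHLKPCKSTGMEVWWWEPFWLMHHLISDGVSV
RCIHCHHNMIGYEFDIDIVFLLANYWSSWGSWTHAERGSTCSWPFYMDDYEDFAVWPLNT
LEAYYFISACPGQMSTPKGMVQKQSKQYMRINRCALAVANWAASSPCKHSCCNFGADPSS
GIGTFVNTLASMDCWEEAPHDAVQSIKQRRLNRYNMHFRSKPVSYSFCRHVFWESKEHQD
VPFEHFTDLQFFRRWNEWASDMGHHVPMERQDKVIPEACTIKRVNWHWPDTPYNWNRQWG
GMVRRDSSRNPLDKRHYISWQNHSCCHDFNRRSTLVWTTPCWSPLWGSPGNN
>I_5
WKMVVYEWISGGIYNPNQGHSFAQRGLCVLHEDLYMLMYITKVHMMQFEKQLTGCDLGKW
RHEVLRTFFRWTPSKKPCGFMVPTGHQHFHLIPCKSTGMEVWWWEPFWLMHHLISDGVIV
RCIHCHHNMIGYKFDIDFVFLLANGWSSWGSWTHAERGSTWSAEFYKDDYEDFAVWKLVT
LEAYYFASACPGQMPTPKMMVQICSKQYMRINRCALAVANWADSSPCKKSCCDFRADICS
GIGTFVNTLAARGKWEESPHDAVQSIKVRDLNRYNMHFRSKPVSYSFCRVVFWESKEHQD
VAFEHFTDMQSTRRWNEWASDPGHHVPMERQDPVIPEACTNKRVNWHWPDTPYNWMRDSG
KCVRRDSSRNPPDKRHYISWQNHSCAHDFNRMSTLVWTTNCWSPLMGSPGNY
>I_6
WKMVVREWISGGIYTPNQLHSFAQRRLWVLHEDLYMLMYITKVHMMQFEKQGTGCDLGKW
RHEVLRTFFRWTPSKWPCGFMVPTGHQHFHLGPCKSTGMEVWWWEPDWLMHHLISDGVSV
RCIHCHHCMIGEEFDIDIVFLLANYWSSWGSWTHAERGSTWSAPFYMDDYEDFAVWPLNT
LEAYYFASACPGQMSTPKGMRQKQSKQYMRINRCALAMANWAASSPCKHVCCNFRADPCS
GIYTFVNTLVSRGCWEESPVDAVQSIKQRDLNRYNMHFRSKPVSYSFCRVVFWESKEHQD
VPFEHFTDLQFFRRHNEWASDCGHHVPMERQDKVIPEGCTNKRVNGHWPDTPYNWMRDSS
GMVRRDSSRNSLDKRHYISWQNHSCAHAFNRNSTLVWTTPCWSPLQGSPGNY
>I_7
WKMVVHEWISGHIYNPNQLHSFAQRRLWVLVEDLYMLMYITVVHMMQFEKQGTGEDLGKW
RHEVLRTFFRWTPSKKPCGFMVPTGHHHFHLIPCKSTGMEVWWWEPFSLMCHLISDGVSV
RCIHCHHNHIGYEFDIDFHFLLFNYWQSWGSWTHAERCSTWSAPFYMDDYEDFAVWCLNT
LEAYYFASACPGQMSTPKGMVQKQSKQYMVINMCALAVANWAASSPCKHSYCNFRADPCS
GIGTKVNTLKARGEWEESPHDAVQSIKQRDLNRYNMHFRSKPVSFSFCRVVFWESKEHQD
VPFEHITDLQFFRRWNEWASSWYHHVPMERQDKVIGEFCTKKRVNWHWPDTPYNWMRDSG
GMVRTDSSRNGLDKRHYISWQNHCVAHTFNRMSTLVWRTPCWSPLMGSPGNY
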
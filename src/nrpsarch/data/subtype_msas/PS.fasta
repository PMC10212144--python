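>PS_0
TELDNYKQEGWNCEVQAKNESTAQTRLWFLLWTYRGLCNVGMRRTNDEQYKREYGPHMEI
RHEYLRTPFFRKSFRDKKNQLTFHTGWPVLCAEMKTVGTLASIAHYQWCMHHDISDGVSW
ECFQDTHERRSTSYYTLRTQKHRWTRMRPFMFDKCDSSTNSPCAMPWHTYLDFAVWECGE
HGGISQLQYFINQAEHCPRAIGHYLHGNALDLPQYCDFKTNTKGPMTEGEDQIQFGMHNN
YIWSFVNTLAHRCISPHCGELFYTGWQVEWYSWHHSDGDWVNYMRVTEEENQDNHDTPQD
VPFENHKRVTVRTVCQWNDWPHTYASDEATMIWRHKWCCYHYDPHTPAHPNDHPWVIHGK
RALGRISARNPLQRENQHDPTTTVCFVTQMPPDRYVWFRVATKSDLQRIPEY
>PS_1
TELDHYKQEGRNCDVQTKGESTAQTRLYFLLWTYRGLCNVGERRTNDVQYKREYNPHCEI
RHEYLRTPFFRKNFRDKENQLTFHTGWAVLCAEMKTWGCLASIAHYKWCMHHDISDGVSW
RCGQDTHERRSTSYYTLRTQKCRQTRMRPFMFDKCDSSLNSPCAMCGDTYLDFAVKEGGE
HGGIYMLQKFKNQAEHCQRAIGHYLHGNACGLPQDCDFQTNTKGPMTEGEDQTQFWMHMN
DIGKFVNTLAHRCYYIHCGELFYTGTQVCPYSWTHSDGDWVNEMRGREEENQDNHDTHQD
VPFENHKRVTSRLVCQWNDWPGTEQSDRATMIWRHKWCCYHYDPKTEAHPNDGPWVIHSK
RALGRDSSRNPLQEENQHDPTTTVCFVTQMPTDRYVWFRVNTKSDLIRIPEY
>PS_2
TELDHYKQEGWNCEVQAKGEYTAQTRLWFLLITYNGLNNVGERRTWDEQYKREYNPHMEI
RHEYLRTPFFRKFFRDKKNQWTSHTGWAVLCAEMKTVGILASIAHYKWCMHHDIVDGVSW
RCFQDTHERRMTSNYTLRTQKCRDTDMRPFMFDKCDSSLNSPIAMCGDTYLDFAVHSCPE
HGGISMLQKFKNQAEHCPRAIGHYLIGNALGLPDYCDFQSNTKGPDTEGEDRIWFWMHMN
YIGKFVNTLAHRCYYIHCGELFYEGSQVWWYSWTHSDGDWVNYMRVGEEENQDNHDTHQD
VPFENLKRVTVRLVHQWNDWPATEQSDRATMIWRHKWCCYHYAPKGEAKPNDHPWVIHSK
RALGRDSSRNPLQEENQHDPTTTVCFVTQMPTDRYVWFRVNTKSDCRRIPEY
>PS_3
TELDHYKQEGWVCEVQAKGESTAQTRLWFLLWTYRGLCNVGERRTGDEQYKREYNPHMEI
RNEYLRTPIFRKFWRDKQNQFTFHTGWAMLEAEYKTVGCLASIAHYKWCMHHDISDGVSP
RCFQDTVERRSTSYYTLRTQKCRNYRGRPFMFDKCDSKLNSPHAMCGDTYLDFAVWEMGE
HGGQSMLQKFKNQAEHCPRAIGHYLHGNALGLPQYCDFQTNTKGPMTEGEDQFQFWMHMN
YIGKFVNTLAHRCYYIHCGNLNYLGWQVWWYSWTHADGDWVNYMIVTEEESQDNHDTHQD
VPFENHKRVTVRLVCQWNDWPHTEQSDRATMVWRHKWDCYHYDPKTEAHPNDHPWNIHSK
RALCRDSSRNPLQEENQHDPTTTVCFVTQMPTDRYVWFRVNTKSDLIRIMHY
>PS_4
TELDHYKQEGSNCEVQAKGESAAQTRLAFLLWTYRGLCNVGERRTNDSQYKREYTPHMEI
RREYLRTPFFRKFFRDKKNQLTFHTGWAQLCAFMKWVGCLASIAHYKWCMHHDISDGPSS
RHFQDTHERRSTSYPTRRTQKCRCTRMRGFMFDKCDSSLNSPCAMCGDTYLDFAKMECGE
HGGISMLQVFKNQAQHCPRAIGHYLHGNALGLPQYCDFQTNTKGPMTEGETQIQFWMHMN
YIGKFVNTLAHRCYYIKCGELFYTGGMFWQYSWTPSDGDWKNYMRVTEEENQRNHDTHQD
VPFENHKRVTRRLVCQWNDWPHTEQSDRALMIWRHKWCYYHYDPKTEAHPNDHPWVIHSK
RALGRDSSRNPLWEENQEDPTTQVCFVTQMPTDRWVWFRVNTKSDLIHIKEY
>PS_5
TELDHYKQEGWNCEVQAPGESTAQTRQWFLLWRYRGLCNVGERRTNDEQYKREYNPHMEV
RHEYLRTPFFRKFFRDKKNQLTFHTGWAVLCAEMKTPGCLAWIAHYKQCMHHDSSDGVSW
RCFQDTHERRSTSYATLRTQKCRNFRMRFFMFDKCDSSLNWPCAMCVSTYGDFAGWECGE
HGGISMLQKFKNQAEHCPRAIGGYAHGNALGLPQYCDFQTFTKRPMTCGEDQIQFWMHMN
DIGSFVNSLAHRDYYIHCGELFYTGWQVWWYFWTESDGDWVNYMGVTEEEWQYNHDTHQD
VPFENHKRVTVRLVCQWNDWPHVEQSDFATMIWRHKWCCYHYDPKTEAYPNDHPWVIHSK
RALGRDSSRNPLQEENQADPTTTVCFVTQMPTDRYVWFRVNTKIDLIRIPEY
>PS_6
TEDDHYKQEGWFCEVQAKGESTAQTRLEFLLWTYRGLCNVGERRTNDEQYKREYCPHMEI
RHEYLRTPFFRKFFRDKKNQLTFHTGWAVLCAEMKTVGVLWSSAHYKWCMHHDISFCVSW
RCFQDTHERRSTSYYTLRTQHCRNTRMRPFMFSKCDSSMNSPCSMCGDAYLDFAVWECGE
GGGISMLQKFKNQAVHCPRAIGHYLHGCALGLPQYCDFQTCTKGGMTEGAKQIQFWMHMN
YIGKFANTLAHRCYYIACGELFYTGWQVWWQSWTHSDGDWVNYMRVTEEENQDNHDTHQD
VPFENHKRVTVRLVCQWNDWPHTEQSDRATMIWRHKWCMYHYDPKTEAHPNKHPWVIHSC
RALGRDSSRCPLQEENSHDPTTTVCFVTQMPTDLLVWFRVNTKSDLIRCFEK
>PS_7
TELDHYKQEGLNCNVQAKDESTAQTRLWFLWWTYRGLCNVGERRTNDEQYKREYNPHFEI
RHEYLRTPFFRKFFRDKKNQLTFHTGWAVLCAEMKTVGCLAWYAHYKWCMHHKISDGVSW
RCFQDTHERPSTSYYTLRTQKCRNTRMRPFMFDKCDSSLNSPCAWCGDTYLDFAVWECGE
HGGISMLQKPKNQCEHCPRAIGHYLHGNALGLPQYCDFQTNLKGPMTEGEDQFQFWMHMN
YIGKFVNTNAHRCYYIHCGELFYTGWQAWWYSWTHSDGDWVNYMRVTEEENQDNGCTHQT
VVFENHQRVTVRLVCQHNDWPHTYQSDRATVIWRHKWCCYHYDFQTEAHPNDHPWVINSK
RALGRDFSRNPLQEENQHDPRTTVCFVTQMPTDRYVWFRVNTKSDQIRIPEY
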
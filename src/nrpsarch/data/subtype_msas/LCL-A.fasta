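>LCL-A_0
IIRFLYCQQTIKTLFVKDGVSTAQQRLWSLLPDRYWQKNSEHREARIDMGGYMEAGQFFW
RHEWLRTVFQHRIDVPKFAFDLLIHHPSVFTIECCDVSKYQKENVATDASHGTCDWYSIC
PWFNYHAWIAHNEFGVISHMDLMNLAEASVESKNLHECQHWMHMNSFTTYMDFAVWPKPT
EAFCMHAAWPHVQFQSQYKKAGTAFPEMQLWYHPYLMENMTWQESIQAKTIFQAEQMFRN
TIGMFVNTLAQRRKRKLDSNSSELWLSSCTHSWDMIGFVWIFFPDQNLYSFWYICGVHQD
VPFEEYMTFLEVWKPMLGANKAPLYHMFSFDRTYGMWDLCSVVPKFTTEIMLTISMQYPP
WFNGRDPSRNPLGAESKMGNHVFTQRYSMTYVMMTKSTTLYGCLHPANMESD
>LCL-A_1
IIAFDYCQQTIKTLFLKIGTSTAQQRNWSLLPDRYWQKFSEHRIARIDMGGYMEAGQFFW
RHEWHRTVFQHRIDVPKFATDLLIHHPSVFGIMSCDVSKVQKENVATDASHGTCDPQSGC
KWGNYHHWIEHIEFGVISHMDLVNCAEASAESKNLHECPHWMFMNKFTTYSDFAVWPKPT
EAFCMHAADLHVQAQNQVKDAGTAFPENQLWYDPFLMENMTWQESIQAKTIFDSEQMFRN
TIGMFVNTLAVNIKRKPDSESSELTLSSCTHSHDMIGFVWCFFHDQNLYSFWYICGVHQK
VPFEEYMTWLEVWKPMLGANMAPLYHMCSFDRTYMMLDLCSVVPKFTTEIPLVISMQYPP
WFVGRDPSRNPLGAEDKMGNHVFTQRYSPTYVMMTKSTTLYGCLHPANMEQD
>LCL-A_2
IIRFLYCSQTIKTLFLKDGVSTAQQVLWSLLYDRYWQKFSEHRIARKDMGGYMEAGKFFW
RHEWLRTVAQHVIDVHKFAHDRLIHHPSVFGNCMCDVSKVQKENNATDASHGTCAPYSIC
PWGNYHVWIAHIEFGVISHMDLVNLAEASVESKNLHECPHWMFMNNFTTYMDFAVWPKPT
QAFCMHAAWPHVQAQSQYKDAGTAFPTMQLWYHPYLMENMTWQKWIQAKTYFQAEQLFRN
TIGMFVNTLAQRQKRKCDSNSSELTLSLCGHSHDMIGFVWIFFHDQNLYSFWYYCGVHQD
VPFEEYMTWLEVWKPMLGANKAPLYHMFSFDRTYMHLDLCSVCPKFTTEIPLTISMQYPP
WFNGRDPSRNPLGAESKMGNHVFTQRYSMTYVMRTKSTTLYGELSPANMEQD
>LCL-A_3
IDRFLYCQQTIQTLFLKDGVSTAQQRLWSLLPDRYWQKFSEHRIARIDMAGYMAAGQFVW
RHEALRTVFQHRIDVPKFAHDLLIHLPSVFGICNCKVSKVQKEHHATDASHGTCDPYSGC
PWGNYHVWIRHIEFGVISHMDLVNLAEASVESKNEHECPHWMFMNAFTTYMDFAVAPKPT
HAFCMHAAWPHVQAQSQYKDAGTAFPEMQLWYHPSLMENMTLQESIQAKTIHQAEQMFRN
TIGMFVNTLAQCINRHPISDSSELTLSSCTHSHDMIGFVWIFFHDQNLYSFWYDCGVHQD
VPFEEYMTWLEVWRPWLGANKAPLYHMFSSDRTYMMLDLCDVVPNFTTEIPRTISMQYPP
WFNHRDPSRNPLGTESKMGNHVFTQRYAMTYVMMTKSTTLYGCLHPANMEQD
>LCL-A_4
IIRFLYCQQTIKTLFLKDGVSTAQQRLWSLLPDRYWQKFSEEGLARVDMGGYMEAGQCFH
RHEWLRTVFQMRYDVPKHAHDLLFHHPSMFGIENCDVSKVQKEEVAIDASHGTCDPYSIC
PWGNYHVWIAHIEFGVISGMDLVNLAEASVESSNLHECPHHMFMNSFTTYMDFAVWPKPT
EAFCMHAAWPHVQAQSQYKDAGTFNPEFLLWYHPYLMENMTWQESIQAKTIFQAEQMFRN
TIGMFVNTLAHHIKRKPDSNSAELTLSSCTHSHDMIGFVWIFFHDQNLYSGWYIPGVEQD
VPFEEYMTWLEVWKPWLYATKAPLYHMFSFDRTYMMLDLCSVVPKFTTEAPLTINMQYPP
WFNGTDPSSNPLGQENKMANHVFTQRYSMTYVMMTNSTTLYGCLDPANMEQD
>LCL-A_5
IIAFLYCQNTIKTLFLKDGVSTAQQFLASLLPDRYPHKFSEHRIARIDMGGYMEAGQFFW
RRQWLRTVFQHRIDVPKFAHELLIHHPSVFGIENCDVSKVQKENVATDRSHGTCDPYSAC
SWGNHHMWIAHINFGVISHMDLVNLAEASVESKNLHECPHWMFMNSFTTYMDFAVWPKST
EAFCMHAAWPHVQAQSQYKDAGEAFPEMQLRYHPYLMENMTWQESIQAKTIFQAEQTFRW
TIGMFVNTLAQRIKAKPDSNQSELTLKSCTHSHDMIGFVWIKFHDQNLYSFWYICGVRQD
VPFEEYMTHLEVWKPMLGANKACLYHMFCFDRTYRMLDLCSVVPKVTIEIPLTISMQYPP
WFNGRDPSRNPLGAECKMGNHVFTQRYSMTCVMMTKSTTLYGCLHPANMEQD
>LCL-A_6
IIRFLYCQQAIKTLFLKDGVSTYQQRLWSLLPDRYWQKFSEHRIARIDMGGYMEAGQFVW
RHEWEHTVFQHRIGVPKFAYDLLIHHPSVFGIYNWDNSKVQKENVATDASHGTCDPYSIC
PSGNYHVWIAHIEFGPISHMDLVALAEASWESKNLHECPHWMFMNSFTTYMDFAVWAKPT
ESFCMHADWPHVQAQSQYKDMGTAFPEMQLWYFPYLMENMTWQESIQAKTIFQAEQMFRN
TIGMFVNPLAQRIKRKPDSNSSELTCSSCTHSHDMDGFVWIFFHDQNLYRFWYICGVHQD
VMFEEYMTWLEVWKPMAGANKAPLYHMFSFDRGYMMLDLCSVVPKFTTEIPLTILMQYWP
WLNGRDPSRNPLGAESKVGNHVFTQRYSMTYVMMTKSTTLCGCLHPFNMEQD
>LCL-A_7
IIRFLYCQQTIKTLFVKDGVSTAQQRLWSLLPDRYWQKFSEHRIARIDMGGYQEAGQFFW
RHEWLRTVAQHRGTVPKWAHDLLIIHPSVFGIENCDVSKVQKENVATDASHGTCDPYSIC
PWWNYHPWIAHIELGVISHMDLVSVAEASVESKNLDECPHWMFMMSFTTYMDFAVWPKTT
EAFCMHAAWPHVYAQSQYKSALTAFPEMDLWYHPYLMENMTFQESIQAKTIFQAEQMFRN
TIGMFVNTLAQRIKRKPDSNPSELTLSSCTHSHDMIGFVWIFFHDQVLYSFAYICGVHQD
PPFEEYMTHLEVWKPMLGQNKAPLYHMFSFCMTYMMLMLCSVVPKFTTEIPLTISMQYPP
RFNGRDESRNPLGQESKMGNHVFTQRYSMTYVMQKKSTTLYGCCHPANMEQD
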
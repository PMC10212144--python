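>bL_0
PRIAQARMYYEIQCAPYYENSYSQQRLWHLRCYHSYIIEPQEWARYANCMADRFNFCEFM
RHEKLRTKMYEDLKHQWKWTMWCCFYRMVTRYSPLYRENNYRFYAHSHGMHHWISDGVSL
RTWISPQNPSDKAQYNVCKSDFHCAYPISKLQQAKHVCTDPLIELKTEGYQDFAVWGWSI
QTNEKPAKEMAWPMWLWMLKDDTPGHPSITKDMVATTYTPGITPHPMNPIRENVVSWAGY
QIGEFVNTLACRYWATDKFCSRQAHCGNNPIKWLCIIEVMLGEFVWYRHHGNSKSLMHQD
WPFEWMTKSNMHMIKFGFRTEAYAVNVWGTEFMIAPEHAQQRGDEKFTNKNELGGFDEDS
APDLRDHSRNPLHYSPDSKIRAFFWMANMKDVRMLILPTKVYTESQMRLTLC
>bL_1
KHIVQARMYYEIQWPPYYEKSYAQQRCWHLRCYHSYIAEPQMWARYANCMADRFNFCNFM
RHVKLRTFFYEDDKHQWKWTMWLHEYRMVTRYSPAYDENNYRFYAHSHGMHHQISDGVSL
ATWISPQNPSDKAQYNVCKSEFQGAYPISALQQAKHGCTDPLIELKTEGYQDFAVWGWSF
QTCEKPAKEMAWPMWLWMLKDDTPGHPSMTKDMVATTYTPGITPHPMNPPRENDVCWAGY
QIGEFVNTLACRYVLTDKFCSRQAHHGNNPIKWLCDWEQMLGEFVWYRHHGRSKSLMHQD
VPFEHMCKSTMHMIKFGFRTEANHVNVWGTEFMIAPEHIQQRIDDKFTNKNQPGGFDEDS
APDLRDHSRLPLHNSPDSKIRAFFWIANMKDVCMAILCTKVDLAGQMRLTLC
>bL_2
THIVQARMYYEIGWAPYYENSYAQKRLWHGECYHSYIIEPPMWAIYANCMADRFNFCAFM
RHEKLRTKFEEDLKHQWKWTMWLCEYRMVTRYSPLYDTNNYRFYAHSHGMYHWISDGVSL
ATWISPQNPSDKAQYNQCKSLFHGAYPHSKHQQAKHVCQDPLAELKTEPYQDFAVWGWSI
QTNEKPAKEMAWPMWLWMLKDDTPGMPSITKDMVATTYTPGPTPHPMNPPRENDVGWAGY
QIGEFRNCLACRYWSTDKFCSRQAHCGNNPIKWLCDIEFMLGEFKWYRHHGNSKSLMHQD
VPFEHMFKSNMHMIKFGFRTEANAVNVWCTAFMIAPEHIQQYIDNKFTNKNQHGGFDEDS
APDLRDHSRNPLHYSQDSKIRAFFWWANMKDVCMAILCTKVDVAGQMRLTLC
>bL_3
KHIVQAKMYYEIQWAPYYEESYAQQRLWHLRCGHCYIIEPQMWARYANCMADRFNFCEFM
RHEKLRTKQYEDLKHQWKWTMMLNEYRMVTRYSPLYDENNYRFYAHSHGMHHPISDGVSL
ATVISPQNPSDKAQYNVCKSRFHGAYPIWKLQQAKHVCTDPLIELKTEGYQDFAVWGWSI
QTNEKPAKEMMWPMWLWMLKDDTPGHPSITKDPVAFTYTPGITPHPMNPPRENDVSWAGY
QIGEFVNRLACRYWLTDKFCSRQAHCGNNPIKWLIDIEVMLGEFVWYRTHGNSKWLMHDD
VFFEHKFQSNMHMIKFGFRTEANAVNVWGTEFMIAPEHIQQRTDEKFTNKNMPGGFDEDR
APDLRDHSRNPLHYSPDSKIRAFFWWANMKDVCMAILCTKVDVAGQMRLTLC
>bL_4
KHIVQARMYYEIQMYPYYENSYAQQRLWHLRCYHSGIIEPQMWARYANCMADRFNFCEFM
RHPPLRTKFFEDSWHQWKWTMWLCEYREVTMYSPLYDENNYRFYAHSHGMAHWISDGVSN
ATWISPQNPSMKAQYNVCKSLFHGAYPISKLQQAKHVCTDPLIELKTEGYQDFAVWVWGI
QTNEKPAKDHAWDMILWMLKDDTPGHPSITYQMVATTYTPGITPHPMNPPRENDWSWAGY
QIDEFVNMLACRYWLTDKFCSMQAHCGMQPIKWLCDIEVMLGEEVWYRHHGNSKSLIHQD
VPPEHMFKSNMRMIKFGFPTEANAVNVWGTEFMIAPEHIQQNIDEKFTNKNQPGGFDEDS
APDLRDHSRNPLHYLPDSKIRAFFWWARMKDVCMAILITKVDVAGQMLLTLC
>bL_5
KHIVQARMYYEIQWAPYYENSYAQQREWHLRCYHDYIIEPQMWARYANCMADRFNFCWFM
RHEKLRTKFYESLKHQNKWAMYLLEYRMEQTYSPPYDENNYRFYAHSHGMHHWISDGVSL
ATWISFQNPSDKAMYNVCKSLFHGRYPISKLQQAKHVCTDPCIELKTEGYDDFAVWGWSI
QTNEKPAFEMAWPMWHWMLKDDTPGHPSVTKDMVATTYTPGITPHPMRPPRENDVSWAGY
QWGEFVNTLACKYSLMDKVCSRQAHCGNIPIKWLCDIEVMLGEAVWYRHPGNSKSLMHQD
VPFEHMFKSNYHMIKFGFRTEANAHNVWGTEFMIAPEHIQRRIDEKFTNFNQPGGFDEDS
APDLRDVSRNPLHYSYDSKIRAGFWWANYKDVCMAILCTKVDVAGQMRLTLC
>bL_6
KHIVQAEMYYEIQWAMYYENSYAQQRLWHLFCYHSYIIQPQFWAPYANCMAHRFNFCEFM
RHEKLRTKGYEALKHQWKQTMWLCEYRIVTRYSPLYDEHNYRFYAHSIGMHHWISDGVGL
AYWIKPINPSDKAQYNVCKSLFHGAYPISKLQQAKHVCTDPLIELKTEGYQDFAVWGWSI
LTNKKCAKEMALPMWTWMHKDDTPGHPSITKDMVATTYTPGITPHPMNPPRENDVSWAKS
QIGEFVNTQACRYWLTDKFCSRQAYCGNNPIKWLCYIEVMYEEFVWYRHHGNSKSLMHQD
VPFETMFKSNMQMIKFMFRTQYNAVNVWGTTFMIAPEHIQQRIDEKFTNKNQPGGFSEDS
APDLRDHSRNPLHYSPDSKIRAFFWWANMKDVCMAILCTKVDVAGQMRLTLC
>bL_7
KHIVQARMYYEIQWHPYYENSYAQQRLWHLRCYHSYNIEPQMWARYANCMADRFNFCEFM
RHEKLRTKFYEDLKHQWKWTMWLCEYTMVTRYSPLYDENNYRFYAPSHGMHHWISDGVSL
ATWISPQNPTDKAQYNVCKSLFHGAYPIKKLQQAKHVCTDPLIELKTESYQDEAVWGWSI
QTNEKPSKEMVWPMWLWMRKDDTPGHPSITKDMVAMTYTPGCTPHPMNPPRENDVSWAGY
QIGEFVNTRACRYWLTDKFCSRQAHCGNTPIKWLCDIEVMLGEFVWYRHHGSSKSLMHQD
VPFEHMFKSNMHMIKFGFRFEANAVNVWGTEFMIAPELIFQRYDEKFTNQNQPGGFDADS
APDLRDHSRNPLHYSPNSKMRAFFWWLNMKDVCMAIWCTKLDVAGQMELTLD
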
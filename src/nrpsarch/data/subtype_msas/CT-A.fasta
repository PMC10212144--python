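>CT-A_0
TCDVLEWHEVDRAGLKGQYQSFAQRRLWGLQYSFKTEPMIYHFAYFRPETDEDMAVIEFD
RHEHLRTLFLANTPRWNPSCTHDPEQKIRHIYTGGMKIYELKIWHYVYMMHHCISDYVSS
SHASKQGHWADRCYMVRFMAIRQINDGTYKPCRLIMACQACDTIFFFSQYADFAVWWAHS
LVLTLNKTKPGGFNCNGYAHTIHQTHYCVYRIPCTFTLTFSEVDYKQDSGSCMRMQVPNF
PIGFFVNTLANRKFWEQQYEAAAKWKKQFMPNKYHPPGCTHWGFPLCFVPDQGWHFYHQD
VPFEQACNTFNRGAIGVIFSYTGQTCAGYHSNTSTNMSEHLQRLRQIRPQVWCAMHDWYG
DRFWRDYSRNPLIWGLVFLLYGHWLNYKRGYYIEWPEGMEVWSKVCCYLLTE
>CT-A_1
TCDVLEWHEVDGAGLKGQYQSFAQRRLWGLQYSFKTDPMNYHFAYFRPETIEDMAVIEFD
RHEHLRTLFLANTPRWNPSFTHDPEQKIRHIYTRGVKIYELKIWHYVYMFHHIIFDGVSS
SHASKQGHWADRCYMVRFMAIRQINDGTYKPCRLDMANQACDTIFFFSQYAYFAVWWAHS
KVLTLNYVKPDGFDCNGYAHTIHQTQYCVYRIPCTFTLTLSRVDYKQDSGSCMPMQSPNF
PIGRGVNTLATRKFWEQQYPAAAKWGKQFTPNKYHPPRCGHWGFPLCFVEDQGWAFYHQD
VPFEQACNTFNRGAIMVCFSYTVQTCAGYHSCTSTNMSTHPQRLWAIRPQVWCAMHDWYG
DRFWRDWSRNPLAWGLVKLLYGHWLNYKRWMYEEWPEGMEVWAKVCCYLLTE
>CT-A_2
TCDVLCWHEVDRADLKGQYQGFAQRRTWGLQYSFKTDPMNYHFAYFRPETYEDMAVIEFD
RHEHLRWLFEANTPSWNPSFIHDPEQKISHIYTCGVKIYELKIWHYVYMMVHCISDGVGS
SHASKQGHWTRRCYMVRFMAIRQKNDYTYKPCRLIMANQACDTIFFFSQYADFAVWWAHS
LVLTLNKTKKDGFFCDGYAHTIHQTHYCVYRIPCTFTLTLSEVDYKQDSGSCMPEQSPNF
PIGRDVNTLANRKFMHQQYEKAAKWKSQFTPNKYHPPGCTHWGFPLCFVGDQGWHFYHQD
VPFEQACNTFNRGSIGVCFSYTGQTCFGYHSNTSTNMSEHPQHLPAIRPQVWCAMCDWYG
DRFHRDYSRNPLIWGLVKLLYGHWLNSKRWYYAEWPEGMEVWSKVCCYLLTE
>CT-A_3
TCDDLEWHEVDRAGLKGQYQSFAQRRLWGLMYSFKTDPMNYHFAYFRCETDEDMAVIEHD
RHEHLRTLFLANTPRINPSFTHDPEQPIEHIYTCGVKIYELKIWHYVYMMHHMISESVSS
SHASKQGHWADRCYMVRFMAIRQINDGTYKPCRLIMANQWCDTIFFFSQYADFIVWWKHS
LVLTLNKTKPDGFRPIGYAKTIHQIHYCVYVIPCTFTFTLSEVDYKQDSGSCMPMQSPNF
PIGRFWNTLANRKFWEQQVHATAKWKKQFTPNKYHPPGCTHWGFPLVFVEDVGWHFCHQL
VPFEWACNTFNRGAIGVPFSYDGQTCAGYHSNTSTNMSRHIQRLPAIRPQVWCAMHDWIG
DRFWRDYSRNYGIWGKVKLLYGHWLNYKRGYYAEWPMYMEVWSKVCCYLLTE
>CT-A_4
TCDVLEWHEVDRAGLKGQYQSFAQRRLMGLQYSFKFCPMNYHFASTRPEFDNDMNVIEFD
RHEHLRQLFLANWPRWNPLFTHDLEQKIRHIYTCGVKIYELKIWHYVYLMHHCISDGVSS
SHASKQGHWADRCYMVRFMAIRQINDGTPKPCRGIMANQACDSIFFFSQYADFAVWWAHS
LVLTLNYTKPDQFNCNGYAHTWHQTHYCVSRIPCTFDLTLSEVDYKQDSGSCMPMQSPNF
PIGRFVNTLANRKFWEQPYEAAAKWKKQYRPNKYHPPGCTHWDFPLCFVEDQFWHFYHQD
VPDPQACNTFNRGEIGVCFSVTGQTCAGYHSNTSTHMSEHPQRLDAIRPQVWCAMHDWYG
DRFWRDYRRNPLIWGLVKLLYGHWLNYKRWYYAEWPEGMEVFWKVICYLLTE
>CT-A_5
TCDVLEWHEVDRAGLKGQYQSFAQRRLWGQQYSFKTDPMNYHFAGFRPQTDEDMAVLEFD
RHEHLRTLFLANTPRHNPSFTHDPEQKIRHIYTCGVKIYELKIWHYVYMMHHCISDGVSS
SHASKQGMPADRCYMVRFMAIRQINTGTYKPCRLIMANQACDTIFFFSQYADSAVWWAHS
LVLTLNKTKPNGFNCNGYAHTIHQTHYCVYSIPATFTLTLSEVDYKQDQGSCMPMQSRNF
PIGRFVNTLANRKLWEQQMEAAAKWKKQITTNAYHPPGCTHWFFPLCFVEDIGWHFYHQD
VPFEQACNTFNRGAIGVCFSYTPQTCAMYHSNTSTNMSNHPQRLPAITPQVWCAMHDWYG
DRFWRDYSRNPLIWGLVKLLYGHWLKYKRWMYAEWVEGMEVWSKVCCYLLTE
>CT-A_6
VCDVLEWHEVDRAGLKGQYQSFAQRRLWGLQYSFKTDPMNYHNAYFRPETDEDMWVIEFD
RHEHLRTLFLANTPRWPPSFTHDPEQKIRHPYTCGVKIYELKIWHYVYMMHHCISDGVSS
SAASKQGHWADRCYMVPFMAIRQINDGTYKPCRMIMANQACDTIFFFSQYYDPMQWWAHS
LVLTLNFTKPDGFYCNGYAHTIHQTHGCVYRIPCTFTLTLSERDYFQESGSCMPMQSPNK
PIGRFVNTLANRKFWEQQYEAAAKWKKQFTPIVQHPPGCTHWGFPLCFVEDVGWHFYHQD
VPFEQACPTFNRPAIAVCFSYTGQVCAGYHSFPSTNMSECPQRLPAIRPQHWCAMHDWYG
DRFWRDYSRNPLIWGLVKLLPGHWLNKKRMYYKEWPEGMEVWMFVCCLLLTE
>CT-A_7
TCDVLEWHEVDRACLKGQYQQFAQRRLWGLQYSFKNDPMNYHFIYFRPETDEDMWVIEFK
RVEHLRTLFLANTPRWNPSFTHDPEQKIRHIDTCGVKIYELKYWQYHYMMHHCHFDGVSS
SHASTQGHWAARVYMVRFMAIRQINDGRYKPCRLIMANQACSTIFFFSQYADFAVWWYHS
LVLTLNKTKPDGFNCNGYNHTIHQTHYCVYEIPCTFTLTLSEYDYKQDSPSCMAMQSPNF
HIGWFVNTFANRKFNEQQYEAAAKWKKQFTPNKYCPPGLTHWGFPLCFVEDQGWHFYHQD
VPFEQACNTFNRGAIGVCFSYTGQTCANYHSPTSTNMKEHPQRTPAIRFQVTCEMHDWYG
DRFWFDYSRRPLIWGLVKLLLVHCLNYKRRYYAEWPEGMEVKSKVCCYLLFE
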
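>Hybrid_0
HCWHGFPHASSMFSGQDTTDSHAQERLWSLKAKMDKQLRHANEMIEHYFKEPWYASWMHG
SREQLRTPFLVNNTLRNQFQFEKKSQVTKKVCLGHLFIQMCRGYKGHYAHHHIISDGVSH
CVLVSDWNGCAERDHWQWHFPYMCPQTFTMNFTGWDFCKCIYLLMPGSWYDDFAVWATGR
HDLYNHWEYNQKYNWLEFMLMFPQMRQVFSYVFIPAYYNHPGDLSTPKVGPFVQYMSAQY
DAGQFVNTLAIRWTMYVNYIEQRLWRNDDEICGINVHMIASRRICYGDSGCPNAAHDHQD
VPFKKWMANEMSHRVEGGLTENHKPSAMTYTIVYTQNCTPFEAVGTSSRICKEFFSMASD
KLHLRDHSRNPLYGCYQDLPKWYNCKLSKNQWFYCRVFQNWIEAKPTMTNCH
>Hybrid_1
HTWFGFPHASSMFSGADTTDSLAQERLWSLKAKMDKQNRHGNFMIEIDFKEPWYASTMHG
RTEQLRTPFLVNTTLRNQWQFEKGWLVTKVVCLGHVFIQDCRGYAYHLAAHHIISDGVSH
CVYISDTNAFAERDHWQWHFPYMCPGTFTTYFTNWDFCKCIKLCMPGSWYDDFAVWATFA
HDLYMHWEYIQKYNWLEFMLMFPVMRQKFSYVSIPFYYNHPGDLSTPTVGPFVQSHSAQY
DIGQFVNTLAIRWTMYVNYIIQRNWRNDDEICGICNHAKASRRTCYGDSGCPNIAHDHQD
VNFEKWDKNEFSHRVEGGLTNNHKPSAMCYTISYDQNGTPFEAVGISSRICKEFFSMASD
KLHMRDHSRNPLYGCYWDLPKWYNCKLSKNQWFYCRVFQNWIEAKLTSTNCH
>Hybrid_2
HRWCGFPHASSMFSGACTTDSLAQERLWSLKAKMDKQLRMGNEMREIYFKEPKLASWMHG
RHEQLRTPFLVNTTLRNQWQFENKSLVTKKVCDGHLFIQDCRGYAGHYAMHHIMSDGVSH
CVLVSDWNGCAERDHSQWHFPYMCPGPFTMYFTGWDFCKLIKLLMPGSWYDDFAVWATGA
HDYYMHWEYIQKYMWLEFMLMFWVMRQFFSYVFIPAYYNHPIDLSTPKVGPFVQYMSAQY
DIGQFVNLLAIRWTMYVNYIEQRNWRNDDEICGICNHMIFSRRTCYGDSGCPNAAVDHQD
VPFEKWDARRMSHRCEGGLTNNHKPSAMTYTISYDQNSTPFEAVGTSSRICKEFFSMASD
KLHKRDHSRNPLYGCSWDLPKWRNCKLSKNQWFYCRVFQNWIECKPTMTNCH
>Hybrid_3
HRWCGFHHAGSMFSGADTTDSLAQERLWSLNAKMDKQLRHGNEMIEIYFKEPWYQSWMHG
RHEQLRTPFLVNTTLRNQWQFEKKSLVTKKVCLGHLFIQDIRGYAGHYAMHMIISDGVST
CVLVWDWNGCMERDHWQVDFPYMCPGTFTMYFTGWDFCKCIKLEMPGSWYYDFAVWATGA
HDLYMHWEYIQKQNWLEFMLMFPVMRQFHSYVFIPAGYNHPGDLSTPKVGPFVQYDSPQD
DIGQFVNTLAIRWTMYVNYIEQRNWRNDDEICGICNHMINSRRACYGDSGCPNAAHDHQD
VPFEKWDTNEMSHRVEGGLTNNHKPSDWTYTISYTQNGTPFEAVGTSSRICKEFFSMASD
KLVKRDHSRNPLYGCYWDLPKWCNCYLSKNQWFYCRVFQNWPEAEPSMTECH
>Hybrid_4
HRWCAFPHASSMFSGADTTDSLAQERLDSLKAKMDKQLRHGNEMIEIYFKEPPYASWMHG
RHEQHRTPFLVNTTDVNQWQFEKKSLVTKKVCLGHLFIQDCRGYAGHYAMHHAISDGVSH
CVLVSDWNGCAERDHWVWHFPYMCPGTFTMYFTGWDGCKCIKLLMPGSWYDDFAVWATGA
HDLYMHWEYIQKYNWLEFMLMFEVMRQFFSYVFIPAYYNHGGDLSTPKVGPFVQYMSAQY
DIGQFVNTLAIRWTMYVNVAEQRNWRNDNEICMICKHMIASNRTCYGDSGCPNAAHDHQD
VPFDKWDANEMSHRVEGGLTNNHGPSAMTYTISYTQNGTPFEAVGTNSRICKEFFSMAPD
KLHKRDHSWNPLYGCYWDLPKHCNCKLSKNHWFYCRVFQNWIEAKRGMTNCH
>Hybrid_5
HRWCGFPHASSMFSGAYTQDSLAQEVLWSLKAKKDKQYRHGNEMIEIYFKEPWYATGMHG
RHEQLRTPFLVNTTLRNQWQFEKSSLVTKKVCLGDLFVQDCRGYAGHSAMHLIISDGVSH
CVLVSWWNGQAERDHWQWHFPYMCPGTFTMYFDGWDFCNCIKLLMPGSWYMDFMVWATGA
HDLYMHWEYIQHYNWLEFMLMFPFMRIFFSYVFIPAYYNHPGDLSTPKVSPFVHYYSAQY
DIGQFVNTLAIRWTMYVNYEEQRNWRNPDEICGPCNHMIASRRTCYGDSGCPNAAHDHQG
VPFEKWDANEMSHRVEGGLRNNHKPSAMTYTIHYTQNKTTFEAVGTSSRICKVFFSMASD
KLHKRDHSRNPLYGCYWDLPKWCNCKLSMNQWFYCRVFQHWIEAKPTMTNCH
>Hybrid_6
HRWCGFPHASNMFSGADTTDSLAQERLWSLKAKMDKQNRRGNEMIEIYFKEPWYASWMHG
RHEQLRTPFLVNTTLRNQWQFEKKNLVTKKVCLNHLFIVDCRGYVGHYAMHHIISDGNSH
CVYVSDWNGCAERDHWQWHFPYMCPGTFTMYFTGWDFCKCIKLLMPHSWYDDFAVWAWGA
HDLYMTWEYIQKYNKLEFMLMFPVMRQFFSYVFIPAYYNHPGDLSTPHVGPFVQYMSAQY
DIGQFVPTLAIRWTMYVNYIEQRNWRNDDEICWICNHMIAARRTCYGDSGCPNAAHDHQD
VPFEKWDANEMSHRVIGGLTNNHKPSAMTYTISYTQNGHPKEAVGTSSRICKEFFSMESD
KLHKRDHSNNPLKGCYWDLPKWCNIKLSKFQWFYCRVNQNWIEAKPTMTNCH
>Hybrid_7
HRWMGFPHASGNPSGADTTDSLAQERLWSLKAKLDKQLRHGNEMIEINFKEPWYASWMHG
RHEQLRTPFLVNTTLRNQWQFEKKSLVTKKVCLDHLFDQDCRGYAGHYYMHHIISDGNSH
CVLVSDWNGCAERDHWCWHFPYMCPGTFTMSFTGWDFCKCIKLLMPGSIYDDFAVWATGA
HDLYMPWEYIQKYNWLEFMLFFPVMRQFFSYVFIPEYYCHPGDLSTPKVGPFVQYMSAQY
DIGQFVWTLAIRWTIYVNYIEQRNWRNDKEICGLCNHMIASRRTCYGDSGCPNAAHDHQD
VPFEKWDANEMSHRVEGGLTNNHKPSAMTYTISYTQNGTPFEAIVTSSRICKEFFSMASD
KLHKRDYSRNYLYFCEWDLPKWCNCKLDKGQWIYCRVFQNWIEAKPTMTNCH
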
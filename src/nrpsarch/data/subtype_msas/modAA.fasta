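>modAA_0
MNSLHGEVGKSSATVISDMHSCAQQRLWLHGIHLEMIYSPRQMQHAGGLWSRFKYPQEIL
RHENLRTSFHHYIYRRNFYTYMLCKPYKMYMYPESPWCMAEVCTANHKRMHHMISDGSSR
KKNNWTVCRWQYRVPWPYFTQSMSTEVPISRVELVVWLSTGNRLSRGYDYPDFAVWQVER
LLYQALGTSKFYHCYQWRHFLNYHCGFKPKDPVCIRYVEEGKIKCMPKNFHWIQLEQHIC
HIGTFVNTLATRLSQESMHGKVKAPGLYVSRYYVYPTGDAPTIICEFIFMYDVSCSGHQD
VTFETIYRRATTGDENCRLQVPNIHKWYEHMSRGSMRTGRHPLDFVHQRSPLMCNIIKAV
EQIGRDMSRNPLTLNAGWLPGGFADNDQQDTWLNSDDMHRGTFWQQYDSNFK
>modAA_1
MNSLHGEVGKSSATVISDMHSCAQQRQWGLGIHLGWIYSPRCMQTAGPMWSRFKYPLMII
RHENNRTLFHHYIYRESFYTYMECKPYKTYMYPESPWCMAEYCTANHLRWHHSVSDGVSR
KKNNWTVCRWQYRVPWEYFTCSMSTEVPWGHYERVVWLPTGNRFNRGYDYPDFDVTQVER
PFYQALGTSKFYHCYQVRQFLNYHWGFKPKDPVCICYVEEGKCKCMPKNFHWIQLEQHMC
HIGTFVNTLATRLSQESMHGTVKAPGLYVWRGYNYPTGAAPTIIGEFWFMYDVSCSGHQD
VPFEMFWRRATRHQENPRLQVPNIEKWYEHTSRGSMRTGRHPLDFVHQPSPLSCNIIKAV
EQSGRDMSRNPLTLNAGWLPMGKQDRDQQDKWLCIDDMHRGTQCQQSDSNFK
>modAA_2
MNKLHSEVKKSSATVISDMHSCAQQRLWGLGIHLWWIYSPRCMQPAMGMWSRFKYPLEII
RHETYRTSFHHYAYRINFYTYMLCKPVKTYMYPESPWCMEEFCTANPLRMHHMISDGVSR
KKNNWTVCRSQYRVPWPYFTQSMSTEVPISRVESVVWLSTGNRLNRGYMYPDFAVWQYEY
LFYQALGTSKFYHCYQWVHFPNYHCGFKPKDPVCIRYVEEGKCKRMPKNFVWIQLEQHPC
HIGRFVNTLATWLSQGSMHGKVKPPGLYVMRYYNYPTGAAPTIICEFIFMYDVSCSDHQE
VPIETFYRRATRGQENPRLQVSNIEKWYEHMSRGSMRTGRQPLDFVHQPSPLSCNIIKAV
EQIGRDMSRNYLTLNAGWLPMGFQDRDQQDAWLCSDDMHRGTFWQQYDSNFK
>modAA_3
MNSLHGEVGKSSATVISTMHSCAQQRLWGLGIHLWTIYSPRCMQTAGGMWSRFKYPLAII
RHENLRTSFHHYIYRSNFYTYMLCKPYKTYMYPESPWCMAEYCTLNHLRMHHSISDGVSR
KKRNWTVCRWQYRFNWPYFPQSMSMEVPISRVERVQWLSTLNRLNRGYDYPDFAVWQVER
LGYQALGTSKFYHCFQWRHFLNYHVGFKPKDPVVIRYVEEGKCKCMPKNFHWIQREQHMC
HIGTFVETLATRLSQEAMHGKIKAPGLYVWRYYNYPTGAAPTIICEFIFMYDASCSGHQD
VPFETMYRRATRGQDNPRLQVPNIENWYECMSRVSMRTGRHPLDFVHQPSPLSCNIIKKV
EQIGRDAPRNPLTLNAGWLPMGFQDRDQQDACLCSDDMHRGTFWQQYDSNFK
>modAA_4
PNSLHGESGKSSATVISDMHSCAQQRLWGLGIMLWWITSPRCMQTAGGMWERFKYPLEII
RFENLRTSFHHYIYRRNFYTYMLCKPYKTYMYPESPWCMAEYCTANHLRMHHMISDGVSR
KKNWWTVPRWQHRVPWPYFPQSMCTEVPISGVERVVWLSTGNRLNRGYDYPDFAVWQVER
LFYYGLGTSKFYHCYQWRHFANYHCGFKPKDPGCIRYVAEGKCKCQPKNFHWIMLEQGTC
HIGTFVNTLATRLSQESMHGKVKAPGLYDWRYYNYPTGAAPTITIEFIFMYDVSCSGHQD
VPFETFNERATRGQENPRTQVPNIEKWYEHMMRGSMRTSRHPHDFVHQPGPLPCNIIKAV
EQIGRDMSRNPLTLKFGWLPMGFQDRDQQDAWLCSDDMHYGTFWSQYDSNFK
>modAA_5
MESLHGEVGKSSATVQSDMHSCAQNRKWGLGIHLWWIYSPRCMQTAGGMWSRFKYPLEII
RHENLRTSFHHYINRRNFYWYMLCKPYKTYMYPESPWCMAQYCTRNHLKMHHMISDIVSR
KKNNWTVCRWQYRVPWPYFIQSMSTEVPISRVERQVWLSTGNRLNRGYDYPDFAVWQVEM
LFYQALITSKFYHCCQWRHFLNYHCGFKPKDYHCIRYVEEGKEKVMWVVFHLIQLEQHMC
HIGTFVNTLATRLSQESMDGKVKAPGLYVWRYYNYPQGAAPTIICEFIFFDDVQCKGHQD
VPFMTFYRRATRGQENPRLQNPNIEKWYEHMSRGSMRTGEHPLDFVHQPSPLSCNIIKAV
EQIGRDMSRNPLTLNAGWLPMGFQGRDQQYAWLCSDDQHRVTFEQQYTSNML
>modAA_6
MNSLHGELGKSVATVISNIHSCAQLRLWGQGIHLWAIYSPRCMPTAGGMWSRFKYPLEII
RHENLRTSFHYYIYRRNFYTYMLCKPYKVYMYPESPWGMNEYCTANHLRMHHMISDGVSR
KKNNWTVCRWQYRVPWPLFPQSMFTEVPISRVERVVWLSTGNRQNRGYDYPDFAVWQVGR
LFYQALGTSKAYHCYQWRPFLNYHCGFKRKDPVCIRYVEEGKCKCMPKNFHWIQLEQHMC
AIGTFVNTLATRLSQESMHGKVKAPGLYVWRYYNYPTGAAPTIICEFIFFYDVSCSGHQM
VPFETFYRRATRGQENPRLFVINIEKWYEHMSRGSMRTGRHPLDFVHQPSPLSCNIIIAV
EQIGRDMSRNPCTLNAGWLPMGFQDRDQQDTWKCSDDMHRGTFWQQYDYNFK
>modAA_7
MNSLHGEVGKSYATVISDMHSCAQQRLWGLGIHWWWIYSPRCMQTSGKMWQRFKYPLEII
RHENLRTSFEHYIYRRNFYTYMLCKPYKTYMYPESPWCMAEYCTANHLRMHHMIVDGVSR
KKNEWTVCRWQYTVPWPYFPQSMSTEVPISRVERVVWLSTGNRLNRGYDYPDFAVWQVVR
LFYQALGTSKFYHCKQWRHFLNYHCGFKPKDPVCILYVEVGKCKCMEKNFHGIQREQAMC
HIGTFVNTLATRLSQESMCGKVKTPGLYVWRYYNYPTGAAPTDICEFIFMYDVSCSGHQD
VPFETFYRRAMRGQENPRYQVPNIEKWYEHMSRGSDRTGGHPLDFTHQPSPLSCNIIKAV
EQISRDMSRNALTLNAGELPMGFQGRDQQDAWLCSDDMHRGTFWQQYDSNFK
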
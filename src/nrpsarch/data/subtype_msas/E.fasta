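>E_0
TPAAVVFADRFTPISLWFYKFCTNDRFIEDDVGMFWICGTFVDHHGISDGVSCARELKVK
FLLPTTINYWAKGVFDIFMDHRDQLLWAKGQAWHMWCLQAATTCIKDVTTKRGRGGSSPG
VQVLMEYNWKPGGPREVNMCSITYGGCGLMIWPCQSFSSYAIEFDFDYCAMRTIGWFTWM
YPLDFIDHARQGFDFTCDCVHHPTHTNGSTQTEKIFVDRVDTPPMMGRGYGDGSADRSVA
TNWVKHYHFDKHARWCFNYLGQCQPADVPPFRPMMFSQFYFC
>E_1
TMAAVVFADRFTPIQLWFYKFCTNDRFIEDDVGMFWIMGTFYDHHMISDGVSCTNACKVK
GLLPTTFNYWAKLVFYIFMLHRDQLLWFKGQAWHMECLQAATTCIKDVTTKRGRGPSSPG
VQVGMEYNWKTGHGREAKMCSITYGGCGLMIWPQQSFSSYAIEKWFDWCAMRTVGWFTDM
YPLDFQDHARQGFDFTCDCVHHPTHTNGSHQTEKIFVDRVDTPPEMGRGYGDGVADRSVA
TNWVCHKHFDGHANWCFNYLGQCQNDDVPPFLPMMFSQFKFC
>E_2
TMAAVVFADRKTPIQLWHYKFCTNDRFIEDDVMMFWICGTFYDHHGISDGVSCTRECKVK
FLLPTTINYWAPGVFYIFMDHRDQLLWAKGQAWHMECLQAATTCIKDVTTKRGRGGSLPG
VQVLMEYHWKEGHYREVKMCSITYGGCGLMIWPCMSLSSYAIEFDFDYCAMRTVGWFTWM
YPLDFIDHARQGFDFTCDCVHHPTHTNGRGQTEKIFKCRPDTPPEMGRFYGDSLADRSVA
KNWVKHGHFDKHARNCFNYLGQCQNADVPPFLPMMFSQTKFC
>E_3
TMAAVVFADAFTPIWLWFYKFCTNDRFIIDDVGLVWICGTFYDHHRISCGVSLTRECKVK
FLLPTAINYWAKGVFLIFMNHRDQLLWAKGQAWHMECLQAATTLGKDVTTKRGRGGSSPG
VQVLMEYNWLEGHGREVKMCSITYGSAGLMIWPCQSFSSYAIEFDFDYCWMRTVGWFTWM
YPLDFIDHARQGFDFTCDCVHHPTHTNGSTQTEKIFVDPVHTPPEMGRGYGDGTADRYVA
TNWIKHYHFDKLLRWCFNYLGQCQNADVPPFLPMWFSQFKFC
>E_4
TMAAVVAADRFTPIQLWFYKFCTNDRFIEDDVGMFWICGTFYDHHGISDGVSCTRECKVK
FLLPTTINYWAKSVFYIFMDHRDQLLWAKGQAWHMECLQAATTCIIGHTTKRGRHGSSPG
VQVQMKYNWKEGHGREVKMCSITYGGCELMIWPCQSFSSWAIEFDFPYCAERTVGWFNWM
PPLDFIDHARQGFDFTCDCVHHPSHTNGSTQTEKIFVDRVDTPPEMGRGYGDGLADRSNA
TNWVKHYHFDKHARWCFFYLGHCQQADVPPFLPMMFSQFKFC
>E_5
TSAAVVFADRRTPIQLWFYKFITNDRFIEDDVGMFHICGYFYDHHGISDGVSCTRECKVK
FLLPGTINYWAKGVFYIFMDHRDVLLWAKGQAWHMECLQAAMTCIKDVFTKRGRGGSSPG
VQVLMNYNWKEGHGREVKMCSITYGGCGLMIWPCQSFSSYYIEFDFDYCAMRTVGWFTWT
YPLHEIDHARAGFDFTCDCVHHPTHTNGSTQTEKIFVDRVDTPPEMGRGYGDGLADRSVA
TNWQKHYHFDKHARWCFNYLGQCQNADVPPFLPVMFSQFKFC
>E_6
TMAAVVFADRFTRIKLWFYWFCTNDRFIEDGWGMFWICGTFYGHHGISDGVYCTREGKVK
FLLPTTINYWAKGVFRIYMDHRDQLLWAKGQEWHMECLQAATTCIKDVTTLRGRGGSSPG
VQVLVEYMWKEGHGREVKYCSITYGGCGLMIWPVQSFSSYVNEFDFDYCAMREVGWFTWM
IPLDFIDHARQGFKFTCDCVHHPTHTNGSTQTEKIFVMRVDTPQKMGRGYGDGLALRSVA
TNWVKQYHFDKHARWCFNYLGQCTNAVVPPFLPMMFSQSKFC
>E_7
SMAAVVFADRFTPIQLWPYQFCTNDRFIEDDVGMFWICGTFYDHHGISDGVSCTRECKVK
FLLPTTINYWAKGVFQIFMDIRDQLLWAKGQAWHMECLQAATTCIKDVTTKRGRCGSSFG
VQVLMEYVWKEGHGREVKMCSITYGGCGLMCWPCQSFSSYAYEFDFDYCAMRTVGWFTWV
CPLDFIDHARQGFDFTCDCVHHPTHTNGSTQTEKIFVDRVDTPPVMGRGYGDGLADRSVA
TNWVKKYHFDKHAQWCFNYLGQCQNAFVPPFLPMMFSQFKFC
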
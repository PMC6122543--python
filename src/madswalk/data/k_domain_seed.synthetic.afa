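>Kseed01
WAEFTGDYRTGSVEWSYTMGSEFFLANDHCWLDTEEPNFVWKICCCAVYY
>Kseed02
WWEFTQDYRTGSVFWWWTMGSEFFLANQHCSLDTENPNFVWKIQCCAVAY
>Kseed03
WWEFTGDYRHGSVWWMWTMQSEFFLANQHCWLFTEWPNFVWKKQCCAVAY
>Kseed04
WWEFTGDYRCGSVEWMWTMGSTFFLANQHCWLDTEWTNFVWKIQSCAVAY
>Kseed05
WWEFTGDYRTGSVEWMWTMGSEFFLANQHCWLDTEWPNFVWKIQCCSVAY
>Kseed06
WWEFTDDYDTGSVEWCMTMGLEFFLANQHCWLDTEWPNPVWKIQCCAVAQ
>Kseed07
AWEATGDYRTGSVEWGWTMGSECFLCNQHCWLDTEWPNRVWKIQCEVVAY
>Kseed08
WWEFTGDYRTGSVEWQWTMGSEFFLANQHCWLDHEWPRFVWKIQCCAVAY
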
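>elga_standin_synthetic mass-matched synthetic stand-in for the 64-aa elgicin precursor (not the deposited sequence)
MKQSELNALIGGSKFDLDAANLGDYTTSCHKSSTAVCGNTSWKQPLVMQRKNLWAYHQPV
REAG
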
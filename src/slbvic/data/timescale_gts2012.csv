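stage,base_age_ma,top_age_ma
Tournaisian,358.9,346.7
Visean,346.7,330.9
Serpukhovian,330.9,323.2
Bashkirian,323.2,315.2
Moscovian,315.2,307.0
Kasimovian,307.0,303.7
Gzhelian,303.7,298.9
Asselian,298.9,295.5
Sakmarian,295.5,290.1
Artinskian,290.1,279.3
Kungurian,279.3,272.3
Roadian,272.3,268.8
Wordian,268.8,265.1
Capitanian,265.1,259.8
Wuchiapingian,259.8,254.2
Changhsingian,254.2,252.2
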
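>ref_archetypal_moebius_YS1_synthetic
MKMSSTALLLAFLAMLLIVS---NTL-------------AVLKE--AASFSIGNGSTKLSSGQTAFAYSLPALSTAGLPVCGETCIGGTCNTAG--CTCSWPVCTRNSLAANGLA
>ref_hybrid_YS2_synthetic
MKMSSTALLLAFLAMLLIVS---NTL-------------AVLKEDTADSGSKGQGTTKLSSGQTAFAYSLPALSTAGLPVCGDTCLGGTCNTVG--CTCSWPVCTRNSLAANGLA
>ref_linear_moebius_YY1_synthetic
MKMSSTALLLAFLAMLLIVS---NTL-------------AVLKESTAASFSIGNGSTKLSSGQTAFAYYLPALSTAGLPVCGETCIGGTCNTAG--CTCSWPVCTR---------
>ref_cyclic_bracelet_HS1_synthetic
MKMSSTALLLAFLAMLLIVSSETLADPLFSHVIGEEALFTNDVASILSWAMEEGALHKLSSGQTAFAHSLPALSTAGIP-CGESCVWIPCITSAIGCSCKSKLCYRNSLAANGLA
>ref_cyclic_bracelet_NS1_synthetic
MKMSSTALLLAFLAMLLIVSSETLADPLFSHVIGEEALFTNDVASILSWAMEEGALHKLSSGQTAFANSLPALSTAGIP-CGESCVWIPCITSAIGCSCKSKLCYRNSLAANGLA
>ref_linear_bracelet_PN1_synthetic
MKMSSTALLLAFLAMLLIVSSATFKD-PN--------DHTIDVANILSSAMEWGALEKLSSGQTAFAPNLPALSTAGIP-CGESCVWIPCITSAIGCSCKSKLCYR---------
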
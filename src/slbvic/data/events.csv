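name,age_ma,older_ma,younger_ma,kind,notes
Laurussia-Gondwana,350,,,lowstand,pre-SLB ephemeral Laurussia-Gondwana connection; area-cladogram root; printed ~350
Bash 3,,321,319.5,lowstand,first ephemeral SLB exposure; onset printed ~321; duration figure-digitised
Bash 5,,318,317,lowstand,second SLB exposure; onset printed ~318; duration figure-digitised
Mosc 3,,313,312,lowstand,figure-digitised
Kas 1,,307,306,lowstand,figure-digitised; Florens fauna / Lower Bonar coal seam
Kas 2,,304.5,303.5,lowstand,figure-digitised; Garnett fauna / Point Aconi lowstand
Sak 1,,293.5,292.5,lowstand,figure-digitised; Asselian-Sakmarian exposure; Bursum Dimetrodon
Art 2,,286.5,285.5,lowstand,figure-digitised; Wolfcampian-Leonardian boundary at its end
Art 3,,284.5,283.5,lowstand,figure-digitised; Elm Creek interval
Kun3,277.6,,,lowstand,sub-threshold small-to-moderate T/R cycle; figure-digitised
Kun3a,277.0,,,lowstand,sub-threshold small-to-moderate T/R cycle; figure-digitised
Kun3b,276.4,,,lowstand,sub-threshold small-to-moderate T/R cycle; base of Blaine Fm; figure-digitised
Kun3c,275.8,,,lowstand,sub-threshold small-to-moderate T/R cycle; figure-digitised
Terminal Kungurian,,275,273,lowstand,terminal-Kungurian SLB exposure; Therapsid Metamorphosis Interval; 2 My window
Roa1,270,,,lowstand,late Roadian regression re-establishing terrestrial regime; figure-digitised
Roadian,,273,270,transgression,early Roadian (early Kazanian) transgression breaking the SLB; onset printed ~273
Garlstorf,,265.1,263,transgression,first Severodvinian SLB break; lower Tapinocephalus AZ endemism; figure-digitised interval
Niendorf,262,,,failed_transgression,lower-magnitude ingression that failed to break the SLB; figure-digitised
Munster,,260.26,259.5,transgression,second Severodvinian SLB break; Pristerognathus AZ endemism; figure-digitised interval
Zechstein,,258,256.5,transgression,onset printed 258; only the first Zechstein cycle modelled
P1 onset,299,,,glacial_onset,figure-digitised
P1 end,294,,,glacial_end,figure-digitised
P2 onset,284,,,glacial_onset,figure-digitised
P2 end,280,,,glacial_end,figure-digitised
P3 onset,271.6,,,glacial_onset,printed: onset younger than 271.6
P3 end,264.2,,,glacial_end,printed ~264.2
P4 onset,259.5,,,glacial_onset,printed 259.5
P4 end,254.5,,,glacial_end,printed 254.5
Tapinocephalus-Pristerognathus,260.26,,,zone_boundary,dinocephalian extinction; printed 260.26
Pristerognathus-Tropidostoma,259.5,,,zone_boundary,printed 259.5
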
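sample_id,group,age,sex
ME030,ME,40,F
ME028,ME,19,F
ME027,ME,65,F
ME029,ME,40,M
ME007,ME,27,F
LC01,LC,43,F
LC02,LC,27,F
LC03,LC,65,F
LC04,LC,42,M
LC05,LC,36,F
HC18,HC,46,F
HC39,HC,26,F
HC10,HC,59,F
HC37,HC,40,M
HC38,HC,31,F
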
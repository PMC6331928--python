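# Packaged 38-cohort structure matching the published multi-site OCD sample
# composition (3,665 subjects: 407/1,498 pediatric/adult patients,
# 324/1,436 pediatric/adult controls; 70 cortical outcome measures).
# Any ScenarioConfig field given here overrides the packaged default.
preset: enigma_ocd
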
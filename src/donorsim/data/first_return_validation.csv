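# Published first-return internal-validation event counts per 1000 donors
# for the current English recall strategy (COMPARE study of English whole-blood
# donors): observed cohort counts alongside the original simulation model's
# predicted counts. Used by the validation report and its worked-example
# arithmetic; the `observed` column is the comparison baseline for
# first-return simulation runs.
sex,category,observed,published_predicted
female,dropout,98,99
female,returned,902,893
female,other_deferrals,49,48
female,donations_over,658,665
female,donations_under,125,114
female,low_hb_deferrals,69,66
male,dropout,66,66
male,returned,934,927
male,other_deferrals,37,39
male,donations_over,801,816
male,donations_under,68,51
male,low_hb_deferrals,27,21
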
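{
 "cxcr2_activities.csv": "5f5a0d00ae2b3490d9b7a0441bd81bb93ab4ed592813a3af7b8707f777d361b9",
 "test_set_predictions.csv": "3aa635b80ef0e72e270a1b1b456f5e01183f3ce6e2b0017785f458a5243366c9"
}
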
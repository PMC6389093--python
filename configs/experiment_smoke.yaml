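# Small end-to-end smoke experiment (~seconds).
n_pre: 500
n_post: 500
daily_capacity: 5
pre_policy: abcd
post_policy: queue
horizon_days: 28
seed: 7
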
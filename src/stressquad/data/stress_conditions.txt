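# Workplace-stress condition lexicon: one phrase per line, matched
# case-insensitively at word boundaries. Lines starting with '#' are comments.
# The default list covers the 15 most frequent stress-related conditions
# reported for employee-review corpora; extend freely with additional phrases.
stress
high stress
pressure
burnout
understaffing
heavy workload
exhaustion
stress levels
overworked
tension
high workload
extreme stress
mental stress
overload
pressure to perform
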
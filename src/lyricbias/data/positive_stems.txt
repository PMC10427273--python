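# Open placeholder positive-emotion stem list (20 patterns).
# One pattern per line; a trailing '*' matches any stem with that prefix.
# This is NOT a licensed sentiment dictionary; supply your own lexicon
# files for real analyses.
love*
happi*
joy*
sweet*
smile*
sunshine
good
nice*
beauti*
glad
delight*
bless*
paradis*
wonder*
gentl*
warm*
hope*
laugh*
pleasur*
friend*
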
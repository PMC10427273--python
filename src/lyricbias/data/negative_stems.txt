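# Open placeholder negative-emotion stem list (20 patterns).
# One pattern per line; a trailing '*' matches any stem with that prefix.
# This is NOT a licensed sentiment dictionary; supply your own lexicon
# files for real analyses.
hate*
sad*
hurt*
pain*
cry
lonel*
fear*
angr*
anger*
tear*
sorrow*
evil*
kill*
damn*
agoni*
miser*
grief*
broken*
worri*
afraid
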
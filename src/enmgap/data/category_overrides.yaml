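# Explicit category assignments for species whose published profile does
# not satisfy the stated classification rule (kept as data, not logic).
"M. urceolatum": wide_endemic
"M. rostratum": narrow_endemic_lowland
"M. rotundatum": narrow_endemic_montane
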
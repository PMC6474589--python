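# CpG probes required by the 353-locus Horvath clock that are absent from
# the Illumina MethylationEPIC (850k) manifest.
cg19945840
cg02972551
cg02654291
cg13682722
cg09869858
cg06117855
cg05590257
cg27016307
cg24471894
cg04431054
cg16494477
cg19046959
cg17408647
cg27319898
cg19569684
cg19273182
cg09785172
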
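# CpG probes required by the 71-locus Hannum clock that are absent from
# the Illumina MethylationEPIC (850k) manifest.
cg24079702
cg07927379
cg21139312
cg14361627
cg18473521
cg09651136
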
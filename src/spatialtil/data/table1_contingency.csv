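biomarker,comparison,class_label,n_high,n_low
proximity,immune_class,adaptive_enriched,283,29
proximity,immune_class,ie_quiet,401,201
consistency,immune_class,adaptive_enriched,199,113
consistency,immune_class,ie_quiet,255,347
lymphocyte_count,immune_class,adaptive_enriched,238,74
lymphocyte_count,immune_class,ie_quiet,209,393
proximity,genomic_instability,agi,330,98
proximity,genomic_instability,ngi,299,119
consistency,genomic_instability,agi,229,199
consistency,genomic_instability,ngi,192,226
lymphocyte_count,genomic_instability,agi,259,169
lymphocyte_count,genomic_instability,ngi,156,262
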
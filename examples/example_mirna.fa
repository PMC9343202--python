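>hsa-let-7a-5p
UGAGGUAGUAGGUUGUAUAGUU
>hsa-miR-16-5p
UAGCAGCACGUAAAUAUUGGCG
>hsa-miR-21-5p
UAGCUUAUCAGACUGAUGUUGA
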
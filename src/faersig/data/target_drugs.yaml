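# Target drug lexicon: canonical generic name -> brand-name synonyms.
bortezomib: [VELCADE]
carfilzomib: [KYPROLIS]
ixazomib: [NINLARO]
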
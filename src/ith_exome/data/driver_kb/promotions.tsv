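gene	aa_change	justification
SRC	Thr524HisfsTer52	frameshift alters the regulatory Tyr530 phosphosite, most likely activating the kinase
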
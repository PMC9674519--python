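purpose,description
treatment,direct clinical care and prescribing
research,ethically approved research use
quality_audit,clinical audit and service evaluation
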
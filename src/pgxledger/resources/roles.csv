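role,description
pharmacist,community or hospital pharmacist
physician,prescribing physician
researcher,approved clinical researcher
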
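>nisin_A
ITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK
>nisin_Z
ITSISLCTPGCKTGALMGCNMKTATCNCSIHVSK
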
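name	mutations	core_peptide
nisin_Z		ITSISLCTPGCKTGALMGCNMKTATCNCSIHVSK
S29A	S29A	ITSISLCTPGCKTGALMGCNMKTATCNCAIHVSK
M4	I4K,P9T,K12L,S29D	ITSKSLCTTGCLTGALMGCNMKTATCNCDIHVSK
M5	I4R,K12W,A15P,A24K,S29Q	ITSRSLCTPGCWTGPLMGCNMKTKTCNCQIHVSK
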
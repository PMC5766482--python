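>I91_reference titin I91 (I27) module, 89 aa, reference numbering for cysteine columns
LIEVEKPLYGVEVFVGETAHFEIELSEPDVHGQWKLKGQPLAASPDCEIIEDGKKHILIL
HNCQLGMTGEVSFQAANTKSAANLKVKEL
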
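identifier	numeral	motif
6.0	I	C1-C2-C3C4-C5-C6
8.0	II	C1-C2-C3C4-C5XC6-C7XC8
10.0	V	C1-C2-C3XC4C5-C6XC7-C8XC9-C10
10.1		C1-C2-C3C4C5-C6XC7-C8XC9-C10
12.0	VI	C1-C2-C3XC4C5-C6XC7-C8XC9-C10-C11-C12
12.1	VII	C1-C2-C3XC4C5XC6-C7XC8-C9XC10-C11-C12
14.0	VIII	C1-C2-C3XC4C5-C6XC7-C8XC9-C10-C11-C12-C13-C14
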
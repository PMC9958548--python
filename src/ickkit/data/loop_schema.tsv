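class	loop1	loop2	loop3	loop4
6.0	C1-C2	C2-C3	C4-C5	C5-C6
8.0	C1-C2	C2-C3	C4-C5	C5XC6-C7XC8
10.0	C1-C2	C2-C3XC4	C5-C6	C6XC7-C8XC9
10.1	C1-C2	C2-C3	C4-C5-C6	C6XC7-C8XC9
12.0	C1-C2	C2-C3XC4	C5-C6	C6XC7-C8XC9
12.1	C1-C2	C2-C3XC4	C5XC6-C7	C7XC8-C9XC10
14.0	C1-C2	C2-C3XC4	C5-C6	C6XC7-C8XC9
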
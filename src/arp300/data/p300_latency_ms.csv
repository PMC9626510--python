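participant,cs_ms,ar_ms
P1,427,478
P2,434,477
P3,437,486
P4,437,487
P5,438,483
P6,436,484
P7,435,482
P8,431,479
P9,431,481
P10,431,481
P11,433,481
P12,436,482
P13,438,485
P14,438,485
P15,436,486
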
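# Notes on `reference_footprint.csv`

This file is a verbatim transcription of the published crystal-plus-MD
hydrogen-bond table for the two simulated complex conformations (A and B).
Empty persistence cells transcribe the source's "(-)" = "no interaction
observed in simulation". 30 records: 6 α1-helix, 8 α2-helix, 16 peptide.

Known internal inconsistencies of the source dataset, recorded here and
deliberately NOT resolved by code:

1. The source figure legend describes Arg157 as a short-lived contact
   observed only in the simulation of complex A, but the table lists
   Arg157^Nη1/2^–CDR2α Glu54^Oε1/2^ with persistence only in the
   **complex B** column (27 %).
2. The same legend names "Arg162" among long-lived complex-A-only
   contacts; no Arg162 row exists in the table (the table has Arg62).
3. One peptide row is printed as "Gln7^O1^" (CDR3α Ser93^Oγ^, Yes, 21/25);
   "O1" is not a standard atom name and is most plausibly a misprint of
   Oε1, but it is transcribed verbatim. Note the table also carries
   Gln7^Nε2^–CDR3α Ser93^Oγ^ (Yes, 17/25) as a separate row.

Any tooling consuming this fixture must treat it as data to be reproduced
byte-for-byte, not corrected.
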
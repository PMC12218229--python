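>pri-let-7a-1 hsa-let-7a-1 stem-loop (miRBase MI0000060) with 25-nt synthetic low-structure pads
ACCACAAACACCAACAACACCAACAUGGGAUGAGGUAGUAGGUUGUAUAGUUUUAGGGUC
ACACCCACCACUGGGAGAUAACUAUACAAUCUACUGUCUUUCCUAAACCAAACAACCACC
AAACAACCAC
>pri-mir-26b hsa-mir-26b stem-loop (miRBase MI0000084) with 25-nt synthetic low-structure pads
ACCACAAACACCAACAACACCAACACCGGGACCCAGUUCAAGUAAUUCAGGAUAGGUUGU
GUGCUGUCCAGCCUGUUCUCCAUUACUUGGCUCGGGGACCGGAACCAAACAACCACCAAA
CAACCAC
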
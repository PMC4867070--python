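>azurin||Pseudomonas aeruginosa PAO1
MLRKLAAVSLLSLLSAPLLAAECSVDIQGNDQMQFNTNAITVDKSCKQFTVNLSHPGNLP
KNVMGHNWVLSTAADMQGVVTDGMASGLDKDYLKPDDSRVIAHTKLIGSGEKDSVTFDVS
KLKEGEQYMFFCTFPGHSALMKGTLTLK
>p28-azurin||
LSTAADMQGVVTDGMASGLDKDYLKPDD
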
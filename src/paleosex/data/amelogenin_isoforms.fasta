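>AMELX amelogenin, X isoform (enamel matrix protein; X-chromosome copy)
MGTWILFACLLGAAFAMPLPPHPGHPGYINFSYEVLTPLKWYQSIRPPYPSYGYEPMGGW
LHHQIIPVLSQQHPPTHTLQPHHHIPVVPAQQPVIPQQPMMPVPGQHSMTPIQHHQPNLP
PPAQQPYQPQPVQPQPHQPMQPQPPVHPMQPLPPQPPLPPMFPMQPLPPMLPDLTLEAWP
STDKTKREEVD
>AMELY amelogenin, Y isoform (enamel matrix protein; Y-chromosome copy)
MGTWILFACLLGAAFAMPLPPHPGHPGYINLSYEVLTPLKWYQSMIRPPYSSYGYEPMGG
WLHHQIIPVVSQQTPQSHALQPHHHIPMVPAQQPVIPQQPMMPVPGQHSMTPIQHHQPNL
PLPAQQPFQPQPVQPQPHQPLQPQSPVHPIQPLPPQPPLPPMFPMQPLPPMLPDLPLEAW
PATDKTKREEVD
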
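cc4f064a9fc9f7e92eb583ca6b88ac803c6e04782e32693c8104c82eac3c936a  table1B.tsv
0efbbcd28989d91b2593f568645dd4f6a34f72b954dc51040bef30e510ab9443  table2B.tsv
0a1e4d4a53fec937930ceeaaa7ebd63a538c99a577212f645834bc6a3f2da71a  table3.tsv
ce47b579c602d8a5e0a7c2fe4f1ebb2ded4daf7ab575d10cab3fc02a6a1d164c  cyclase_synthetic.tsv
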
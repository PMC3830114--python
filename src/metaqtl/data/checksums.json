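{
 "studies.tsv": "c25197c78b90ceb01c5c8d2acc3611f3f1601a8b6cf918e9276ad3f28c0672bf",
 "trait_counts.tsv": "2fdd947b6aa35bca218f76d0fa9a5d6bd105ceae6376a13e34f91c67d29a0bcb",
 "clusters.tsv": "54d447fca2c1a1a64650482a50e46dfdc87d22aec23fe6e51e425d85495f3e00",
 "hotspots.tsv": "4322ec8fb556a747f10fc1c007b0c4765308c0b8d471373590e1e328f1ae56d6",
 "chromosome_tallies.tsv": "54b5792058aadfe6e3558fddf5da9072fea7eb61c2398622915d8c1d555f049d"
}
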
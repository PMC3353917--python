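set,protein_id,hit_id,rmsd,z_score
misclassified,00927,1ugg-B,2.5,4.4
misclassified,00084,2zyz-A,2.9,4.3
misclassified,00707,1w36-F,1.8,4.1
misclassified,00637,2it3-B,3.0,4.0
misclassified,00905,21ah-A,3.8,4.0
misclassified,00198,2ugi-B,2.9,3.8
misclassified,00403,3kii-A,2.8,3.8
misclassified,00135,3gtd-D,3.0,3.6
misclassified,00229,3rk6-A,2.8,3.5
misclassified,00282,3qwh-A,3.4,3.5
misclassified,00727,2waq-E,3.2,3.3
misclassified,00585,3qnm-A,2.8,3.2
misclassified,00612,3icy-A,3.1,3.1
misclassified,00892,3p1v-A,3.2,3.1
misclassified,00165,1n61-B,3.5,2.6
misclassified,00301,1wlz-D,2.9,2.6
misclassified,00746,1th5-A,2.8,2.6
misclassified,00514,1qyz,3.0,2.4
misclassified,00766,3ef6-A,3.1,2.4
misclassified,00296,3sbl-B,3.1,2.3
misclassified,00797,1kh0-B,3.0,2.2
misclassified,00906,3kcn-B,3.0,2.1
misclassified,00398,3bxj-B,2.8,1.6
misclassified,00083,1lsh-A,4.0,1.5
misclassified,00687,3n2o-A,3.3,1.5
misclassified,00391,1s7o-C,3.1,1.4
misclassified,00708,2ooy-A,3.4,1.4
misclassified,00343,2jge-A,3.4,1.3
misclassified,00499,1zql-C,4.0,1.2
misclassified,00174,no chain,n.a.,n.a.
misclassified,00236,no chain,n.a.,n.a.
misclassified,00102,no chain,n.a.,n.a.
correct,00060,2fu2-A,2.9,3.5
correct,00145,2zrr-A,3.6,3.5
correct,00070,1utx-A,2.7,2.8
correct,00080,1zgh-A,3.4,2.8
correct,00001,1bgw-A,3.9,2.6
correct,00090,2zkm-X,2.7,2.6
correct,00095,2zlm-A,3.1,2.6
correct,00130,2vlg-C,3.2,2.6
correct,00055,2c41-B,3.3,2.5
correct,00025,1sfu-A,4.2,2.3
correct,00030,1f7u-A,3.4,2.2
correct,00045,3oee-N,3.9,2.2
correct,00115,2ld7-B,4.6,2.2
correct,00050,3e26-A,2.9,2.1
correct,00065,2i5u-A,4.0,2.1
correct,00015,3tl2-A,3.5,1.8
correct,00136,3pe3-A,3.2,1.5
correct,00150,1vfg-B,3.2,1.4
correct,00010,3so8-A,2.9,1.3
correct,00040,2vhv2-B,3.2,1.1
correct,00110,2jvg-A,3.9,1.0
correct,00005,1lol-A,2.9,0.9
correct,00035,3kgo-B,3.8,0.9
correct,00085,3p9x-A,3.3,0.8
correct,00125,2lc0-A,2.8,0.8
correct,00155,3nnq-A,3.8,0.3
correct,00020,no chain,n.a.,n.a.
correct,00100,no chain,n.a.,n.a.
correct,00105,no chain,n.a.,n.a.
correct,00120,no chain,n.a.,n.a.
correct,00140,no chain,n.a.,n.a.
correct,00075,no chain,n.a.,n.a.
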
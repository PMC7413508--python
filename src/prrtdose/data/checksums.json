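{
 "phantom_mean_doses.csv": "cdb71073bf8a65b4392b82334db62f6bc4d4038ec7dde3f7e85e6a18644a6397",
 "sample_a_doses.csv": "b273856fab90e5b44896d976f16546463fac0f155436aa8067608d5f5ed2e3ed",
 "sample_b_doses.csv": "6fc1f1f86dc967392cc4d1356a1b8a70d611b1e39681f17ae47f07ae5b87fe48"
}
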
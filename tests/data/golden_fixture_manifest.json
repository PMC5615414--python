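{
  "annotations.tsv": "481b98b9e672ad908b696f5b1622f7a5899cfd78ee89d65119b89047d09f4180",
  "corpus.jsonl": "426a4e8c266ca9536eb680964b27dc8b49107e1e760e70622e43b18be05697cd",
  "disease_lexicon.tsv": "cb4d601e7009f748e9a5a0664e64eb9ed751121492d67b115a02afc83c034ce6",
  "go.obo": "7d04e073aa23a5f4a1223ad7387fd4029bca364ea65eec7dc6e55a90c2d7f918",
  "ground_truth.json": "86249c1d0a6f9245a1ddd4aaa549dc627278e63fbc9a55b6bf1e4be24dc04cad",
  "mirna_lexicon.tsv": "0cc3fa91885eaeabf20c744eb0357f1622b713028405aae1f732d8ac8cf62f89",
  "pipeline.cfg": "0d0e216a0d90f381b19e28aefba1038153364c11a506891642393c7d3317fefa",
  "regin_a.tsv": "e2cff01031731f8a4ea206e0a413e733f6eea5d3272ed36b309160e95321b3ef",
  "regin_a.xgmml": "dcdd8fd54a1bf1745d33ff1a5385d1b3a695e9a1e742dfe7852d7d161ec6daa5",
  "regin_b.tsv": "99236dcc04b44b97d37670fe7365979158eff3daf705b85a4b6b18feeab7b094",
  "regin_b.xgmml": "adf2b35a48ac88c2a30a6ad2d4bfa299440912b9a99614620f90d20ecccffdc9",
  "regin_c.tsv": "2b5fa31d5b7e9a481f8238a7f98f33ad91c3de2098cbe803c160405c224b53a5",
  "regin_c.xgmml": "41f720ab9906feb553c290f3c86596b4a885171769e0df12212d0dbbe3315b3f"
}
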
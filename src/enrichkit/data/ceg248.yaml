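# Core-eukaryotic-gene reference: four conservation categories totalling
# 248 genes.  Gene identifiers are positional placeholders (the module only
# needs category membership); replace with a real id -> category table if
# one is available.
name: CEG248
categories:
  - name: category_1
    n_genes: 66
  - name: category_2
    n_genes: 56
  - name: category_3
    n_genes: 61
  - name: category_4
    n_genes: 65
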
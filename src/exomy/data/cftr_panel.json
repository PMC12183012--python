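{
  "kit": "CF-EU2v1",
  "transcript": "NM_000492.4",
  "comment": "User-editable screening-panel definition. The full 53-variant commercial kit content is not bundled; the variants listed here are the panel members and non-members needed for kit-membership and enrichment-coverage logic, with curated GRCh37 positions (0-based, half-open).",
  "variants": [
    {
      "cdna": "c.350G>A",
      "protein": "p.(Arg117His)",
      "legacy": "R117H",
      "chrom": "chr7",
      "start": 117171028,
      "end": 117171029,
      "genomic_hgvs": "Chr7(GRCh37):g.117171029G>A",
      "in_kit": true,
      "severity": "mild",
      "deep_intronic": false
    },
    {
      "cdna": "c.1521_1523del",
      "protein": "p.(Phe508del)",
      "legacy": "F508del",
      "chrom": "chr7",
      "start": 117199645,
      "end": 117199648,
      "genomic_hgvs": "Chr7(GRCh37):g.117199646_117199648del",
      "in_kit": true,
      "severity": "CF-causing",
      "deep_intronic": false
    },
    {
      "cdna": "c.1210-11T>G",
      "protein": "p.?",
      "legacy": "5T",
      "chrom": "chr7",
      "start": 117188683,
      "end": 117188684,
      "genomic_hgvs": "Chr7(GRCh37):g.117188684T>G",
      "in_kit": true,
      "severity": "T/TG-modifier",
      "deep_intronic": false
    },
    {
      "cdna": "c.3484C>T",
      "protein": "p.(Arg1162*)",
      "legacy": "R1162X",
      "chrom": "chr7",
      "start": 117267590,
      "end": 117267591,
      "genomic_hgvs": "Chr7(GRCh37):g.117267591C>T",
      "in_kit": true,
      "severity": "CF-causing",
      "deep_intronic": false
    },
    {
      "cdna": "c.617T>G",
      "protein": "p.(Leu206Trp)",
      "legacy": "L206W",
      "chrom": "chr7",
      "start": 117175338,
      "end": 117175339,
      "genomic_hgvs": "Chr7(GRCh37):g.117175339T>G",
      "in_kit": true,
      "severity": "mild",
      "deep_intronic": false
    },
    {
      "cdna": "c.3718-2477C>T",
      "protein": "p.?",
      "legacy": "3849+10kbC>T",
      "chrom": "chr7",
      "start": 117265099,
      "end": 117265100,
      "genomic_hgvs": null,
      "in_kit": true,
      "severity": "CF-causing",
      "deep_intronic": true
    },
    {
      "cdna": "c.1680-886A>G",
      "protein": "p.?",
      "legacy": "1811+1.6kbA>G",
      "chrom": "chr7",
      "start": 117229599,
      "end": 117229600,
      "genomic_hgvs": null,
      "in_kit": true,
      "severity": "CF-causing",
      "deep_intronic": true
    },
    {
      "cdna": "c.2472del",
      "protein": "p.(Asn825fs)",
      "legacy": null,
      "chrom": "chr7",
      "start": 117232692,
      "end": 117232693,
      "genomic_hgvs": "Chr7(GRCh37):g.117232693del",
      "in_kit": false,
      "severity": "mild",
      "deep_intronic": false
    },
    {
      "cdna": "c.413_415dup",
      "protein": "p.(Leu138dup)",
      "legacy": null,
      "chrom": "chr7",
      "start": 117171089,
      "end": 117171092,
      "genomic_hgvs": "Chr7(GRCh37):g.117171090_117171092dup",
      "in_kit": false,
      "severity": "mild",
      "deep_intronic": false
    },
    {
      "cdna": "c.1367T>C",
      "protein": "p.(Val456Ala)",
      "legacy": null,
      "chrom": "chr7",
      "start": 117188851,
      "end": 117188852,
      "genomic_hgvs": "Chr7(GRCh37):g.117188852T>C",
      "in_kit": false,
      "severity": "mild",
      "deep_intronic": false
    }
  ]
}
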
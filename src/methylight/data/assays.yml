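# Published p16 (CDKN2A) MethyLight assay definitions plus the COL2A1
# reference assay. Uppercase C/G mark CpG-derived methylation-discriminating
# bases; `orientation: opposite` marks oligos printed for the face of the
# amplicon opposite the conventional one for their role (recognisable by
# lowercase c residues that could not survive bisulfite conversion on the
# assayed strand itself).
assays:
  - name: p16-ML-70bp
    target_strand: antisense
    reference: false
    nominal_length_bp: 70
    forward:
      name: ML-Primer-F1
      sequence: "tggag ttttC ggttg attgg tt"
    reverse:
      name: ML-Primer-R1
      sequence: "aacaa cGccc Gcacc tcct"
    probe:
      name: ML-Probe-1
      sequence: "accCg acccC gaacC gCg"
      label: "6FAM/TAMRA"
      orientation: opposite

  - name: p16-ML-115bp
    target_strand: sense
    reference: false
    nominal_length_bp: 115
    forward:
      name: ML-Primer-F2
      sequence: "CgCgg tCgtg gttag ttagt"
    reverse:
      name: ML-Primer-R2
      sequence: "tacGc tcGac Gacta Cgaaa"
    probe:
      name: ML-Probe-2
      sequence: "gttgt ttttC gtCgt Cggtt"
      label: "6FAM/TAMRA"

  - name: COL2A1-reference
    target_strand: sense
    reference: true
    forward:
      name: COL2A1-F
      sequence: "tctaa caatt ataaa ctcca accac caa"
      orientation: opposite
    reverse:
      name: COL2A1-R
      sequence: "gggaa gatgg gatag aaggg aatat"
      orientation: opposite
    probe:
      name: COL2A1-Probe
      sequence: "ccttc attct aaccc aatac ctatc ccacc tctaa a"
      label: "6FAM/BHQ1"
      orientation: opposite
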
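{
 "contig_id": "SIM_CONTIG_004",
 "features": [
  {
   "end": 650,
   "id": "SIM_CONTIG_004_gdiv",
   "product": "divergent neighbor protein",
   "start": 50,
   "strand": "-"
  },
  {
   "end": 1400,
   "id": "SIM_HOM_004.1",
   "product": "transcriptional regulator",
   "start": 800,
   "strand": "+"
  },
  {
   "end": 2050,
   "id": "SIM_CONTIG_004_gdown",
   "product": "co-transcribed downstream protein",
   "start": 1450,
   "strand": "+"
  }
 ],
 "regulator_id": "SIM_HOM_004.1",
 "sequence": "TGTTGTTAATCTGGGCTTACTATTGTTCGGGGGCTAGGCTCAAAGGAAAGCGCTTTTGTGCTCATAATTGTAACAACTGGGGGGAGAACGGGCACGGTGTGCGGAAGCGGAACTCCGGCGAAGCTCGTGCCACCAATTTACTACCTAGTATGCTCATGCAGATTAGTATTTGTGACTCAGGACACCGGCCCTTAGGCGTATCGGAGAGTTACAGGCTCTCGTTTAAATCAGTGGGCATAGCAGTGTTGCGCATATCAAATCTTGTCACATAAATAGTGTCTGGCTATTCCGGAAAAAGCTGTCCGGCCAGTTCCCCAAAAAATTTCGAGGTCAGAGCCACATGGCGAAGGGCCTGCGAACATACGGTGTTGCAACACGGATATCAGGTATCCAAGCGTCGGTCGAAAGTGCCGTCCTCAAGCCCAACCCCACCTGTCCTTCTGAGGCGCGTACGAGCTATACATTTATAACATGCAAGATTCACTCCGTTGTTACAGTGCACCGCAGAACCCGACTTGACAACTTGGACAGGGAGCGAGTCGTAATTTTACTCAGGATCGTAGAAAAGTATACCTATGAGGATGATCGCTCGGTTCAATTCGAACTGTCCCAACCCAACTCGGCCGAGCCAGTTCCCAAGTGGAAGAGCGGACAGCAAACGCGCTTCCCATATTCTCCTAACTCCAACGACTCCAAGATCCCACGAGCCTTCGATCTTGGTCCGTCTCGACGTTATACCACTAAGTTCCAGTTTTGCCGTTATCAGCCGAACTTATTCGTTGCAGGTCCCATCTTAATTGTGTGTCCGGAAGCGCTAGTTAGAGTCTCACGAAAATCGCAGGCAGAGTGAGGTTCCAGGGTTCATGGGACGAGCAGTGTAGGCAACCATAGGGTTGCGCCACTGATCCGCCTTACCAGAACCATTGAGAGTCACATTCTGTAACCTCGAACGTGCGCCATTAGCGCTTGGCCGCAGTTGGCCTCATCATGAAACAAGTGACCGTTGTCTTGCTTGGCAACGCCTCAAGGTCCCAGCGAAGCCCGTCCTATTGAACTCGACACCTGCTTACTACACGTTTCATACGCGTCTACTCTCACCGCCCGCGTAGACGTGAAGGTATGTAGCCGAATTTACAACGCCTGAAGTTTGGAAGCGATTACAACAGCACTTTGTTTCGCGTGTACTGATACACCCCTGGTGTTCACGACCCGCCTCCGCCGCAGGGACCAATTACTAAAGTAACCTTCAGCACGGATGCAGGATGAAAGTTTTGGCTCATCACTTGTGTAAGGCACGACTGGATTGCAAAACACAAGCCATTTACACTTCAACAGTAGAGGGTTTAGATGTTCGTCCTCGAACGACCTGAATCTCCTCCTTTCCCCAAAATGATGACAGGGAATGAATTTCACGTGCATGTTTTTGCGGCCCGCGGCGTTAACTGAGAGATAGCATCATCGAGAGTTGTAACTGGGCAGAAGGCTATACTTCTGCTGTTAATGTGGCAAAAGTATAAACTACCCGAAACCTTTCGCGTACATTTCCCCCCCATCCCGTCACGTATACTAGGAAATAGCGTCTTTCCTGTACGTCTGCATCGTTACACCTTGTCACTACATCATAGTGCACGATCGGATAACAATTAAGTCCTGAGAGCCCGTTTCGCGGACATTCTCTCCGTGCTATCGCGGGTTTTGTAGTCCACGGATGCAGATCTCGTTTGCGTCAATGTATGATGATCGCAGAATGTAGGTAGCGTGCAGAGTCAATATTAAGTAACAGTCTTGCTGCTAAGTGAATCATGTGGTAGGATATCCATCTTTTTGCGTAAACCTGATTACTGCGAAGCCAAGGGGTTTTTACTTCTAAATCTTGGAGGTGTCATTCAAGACGATTGTGTTACCGTACGAACTCACGTGGTACCAGCGCAGGCCATCGGTAGTACTCGCTTGCTTGGTGGCGACTACATGCGGTTTATCCCAAGGATCTAGGTCGCGAAGTCGAGATTAACTTGAGGACTTCATACCGATTTTCCACGATGCATATATTTACTCCCTCCTATTGGCATAAAAATACCGTGACATGTCGAACGACTGCCG"
}
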
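{
 "ancestral_protein": "TMRDRNFSMRTGTYMRSKTKVSMETPNRYMIVPLELWGYWTHSQVKPWWWDACYKPKCWLHADMSEMIQHVPETPWWHQNKATICYKDKVRQGGGSTGHVYCGDISNKFDSMAGQMRRDVNCYNFYALASSCGVGNMVRSCVLCCRVEGGVHQNKPFWWALEKIVTGMIMWSCQSGRCCLKVTNMCEKKIMNINDYMHKK",
 "per_homolog_offsets": {
  "SIM_HOM_000.1": 51,
  "SIM_HOM_001.1": 51,
  "SIM_HOM_002.1": 51,
  "SIM_HOM_003.1": 51,
  "SIM_HOM_004.1": 51,
  "SIM_HOM_005.1": 51,
  "SIM_HOM_006.1": 51,
  "SIM_HOM_007.1": 51,
  "SIM_HOM_008.1": 51,
  "SIM_HOM_009.1": 51,
  "SIM_HOM_010.1": 51,
  "SIM_HOM_011.1": 51,
  "SIM_HOM_012.1": 51,
  "SIM_HOM_013.1": 51,
  "SIM_HOM_014.1": 51,
  "SIM_HOM_015.1": 51,
  "SIM_HOM_016.1": 51,
  "SIM_HOM_017.1": 51,
  "SIM_HOM_018.1": 51,
  "SIM_HOM_019.1": 51
 },
 "planted_operator": "CAAGAGCCTTCGCTCTTG",
 "query_accession": "SIM_QUERY.1",
 "region_offset": 51,
 "region_start": 650
}
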
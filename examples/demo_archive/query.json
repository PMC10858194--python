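{
 "accession": "SIM_QUERY.1",
 "protein_sequence": "TMRDRNFSMRTGTYMRSKTKVSMETPNRYMIVPLELWGYWTHSQVKPWWWDACYKPKCWLHADMSEMIQHVPETPWWHQNKATICYKDKVRQGGGSTGHVYCGDISNKFDSMAGQMRRDVNCYNFYALASSCGVGNMVRSCVLCCRVEGGVHQNKPFWWALEKIVTGMIMWSCQSGRCCLKVTNMCEKKIMNINDYMHKK"
}
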
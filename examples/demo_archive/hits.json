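[
 {
  "accession": "SIM_HOM_000.1",
  "coverage": 100.0,
  "percent_identity": 74.5,
  "protein_sequence": "TMRDRNFSVRTGTYMVSKTKVSFHTPNRYMPVPLELHGYWTHIQCKPWWADEGYKPKCWWPAKMSEPIQHVPETQWSSYNKASICYLDKVRQAEGSHGHVYCLDILMAFMSMAGVMRRDIQCYNFYALASSCGQGNMVVSCKLCCRGIYRVMQNFPFMWAHEKIVTGVDKWSCQSGRCCFKGTNMMENKAMNINDYMHKK"
 },
 {
  "accession": "SIM_HOM_001.1",
  "coverage": 100.0,
  "percent_identity": 73.5,
  "protein_sequence": "TMRDYNFSMQVGTKMLSKTKVKVETPWIYMKLPEELWGYWEHDQSKPPWWDALYKPKCWLHAAMQEMIQHVRECPIWHKNKAQICYTCIVRQGTGSWGHVLCGDISKKFDSCAGQMLLDVNCYNFEDPAHSYGVGNMVRSCMLKCRQDGGVHQNKPFWWYLEKIVTGMIWWNLQSGEQCSKCTNMCEKKIMNHNHYMHKK"
 },
 {
  "accession": "SIM_HOM_002.1",
  "coverage": 100.0,
  "percent_identity": 80.0,
  "protein_sequence": "TMRDRGFSMRTGGIMRSVYKVSMWTSIRYMIVKLEGWGYWRHSQWKPWSWDACYKPKCWLHAWMSEMIRKVNETPWWIQNKATICYKDKVRQGGHSLIHVYCGDISNKLDSYAIQMRRDVSCYNFYALESSCFVGNMLRSCVLCCRVEGWLHQNKPFWWKLHIIVTGMIMWSCFYGRCCLKMTNDLEKKIHNIMDYMHKK"
 },
 {
  "accession": "SIM_HOM_003.1",
  "coverage": 100.0,
  "percent_identity": 84.5,
  "protein_sequence": "TMRDRNFSMRTTTYMRLKTRVHMQTPNRYMIVPLALEGYWTHSQVKPWWWDACYKPICWLHADMSEMFQHVPETPWNHQNKATICKKDKVRQGGGSTSMVVCGDISNFFDSMAQMLRRDVNCYNFNALASSGGVGMMVRSCVLCCRVEGGVHENKMPWWALMKIYTGMIMWSCQSGMCCLKRTNMCEIKIMNINDYMYDK"
 },
 {
  "accession": "SIM_HOM_004.1",
  "coverage": 100.0,
  "percent_identity": 80.0,
  "protein_sequence": "TMRDRWFSMRTGTYTISKTKVSMETPNRYMQVPFELWGYQTHSQVEFWWWWACYKPKEWLHADMSEMIYHDPETPHWHYNKARICYKDKVRQGGGHTGHVYCVDISNKFISTAHEMRADVNCWNFVALASSCGVGNMVRSCVLCCYVQGVVHEVKPFWWALEKIVTGMIMPSDGSGICCLKVTNMCEKSIMNINLMLQGY"
 },
 {
  "accession": "SIM_HOM_005.1",
  "coverage": 100.0,
  "percent_identity": 76.5,
  "protein_sequence": "TMHDRNFSMRTGLYMRSKTKVYMETQGRYMPVPLELWGYDTHSFVKFWWWDACDQPGPWLIADESENKQEIPMTGWYHENKAQICYKEKVRQMGGSTGTVHCGDISNKSDSMAGQWRRDVNCYNGYALASSCGGGNQVKSCVLCCRVERGVHQPKPFSWALEPIVTGMIMWGYESGRCCLKYCNWCEKKMMNINTYMHKL"
 },
 {
  "accession": "SIM_HOM_006.1",
  "coverage": 100.0,
  "percent_identity": 76.5,
  "protein_sequence": "VMRDRNFSIRTGTYMPSYTKQSMERPMRVMIVPLEMFAGWTHSQMKPCSWHALYKVKCWEHADNSEMPSHVDETPWWHHNKATICKKDKVRQGGGSTGHVYCGTISNKCDSKAGQERNDVNCYNFYALSSSCGVSNYVFSCGWCCRANGGVHKNKPFLWANEKIRTGMIMWSCYSGRFCLKRTNMPSKKIMNINDYMHKK"
 },
 {
  "accession": "SIM_HOM_007.1",
  "coverage": 100.0,
  "percent_identity": 81.5,
  "protein_sequence": "TTRYRNFSMRTGPYMRSKTPVSMETPNRYMIVPLELWGYDTHSQCKPWWWDACYWLKCELHADMSEMDQHVPETPWWHQNYAEICWKDKVRWGGGSTFHVYCRRISNKWDSMAGQHRRDVNCYQFTAQASSCGVGVMVRSCKLCVRVEGGVHYHKWIWWALEKIVTGMYMWSCQYGRCGLKVLNCCEKVICNSNDYMHKK"
 },
 {
  "accession": "SIM_HOM_008.1",
  "coverage": 100.0,
  "percent_identity": 83.0,
  "protein_sequence": "TMRDRNFSMRTGTYYRSKTGVSMCTPNRIMIVWLELKGYWYHSQVKPWWCDACYKPKCWLTSDMSEMIQHVPETPWVHQNKLTICYKEKVRQGGGGTGHVYTGQISWKTTSKAGQMRRTVNCYNFYALASSHEVGNMVNSCMLCCRVEGGVSENKPFWWALEKIVIGMIMWSCQSGRCCLKVGNRQNKVILNINDYMHKK"
 },
 {
  "accession": "SIM_HOM_009.1",
  "coverage": 100.0,
  "percent_identity": 77.5,
  "protein_sequence": "TMRDRNFSFRPSTYMRSVTKVSGETPNRYMIVPLELSIYWTHSQVKKWWEFVCYKPKCNLHADSSEMIQPVPHTPVWHQNKATICYKDKVRGGGGPTGHVYWGDIMHKFDSTAGQMRIDVNCYNIYALASSCAFGTLVRSWVLHCRIEGGYHQNRVFWWALQKDVVGMIMWKCQSGRCCLKVCNMCEEKIDFINDYSEMK"
 },
 {
  "accession": "SIM_HOM_010.1",
  "coverage": 100.0,
  "percent_identity": 75.5,
  "protein_sequence": "TMRDNNFSMRTVTPMDSKTSRSMCTPDRYMIVRLQGWGPWTHSQVKPNWRDACYKPMCWHYSDMSLMIQHVPATFWFHQTKATICTKDKERQGGGSTCDVYCGDISNKKDSMAGQMRADVNCYVFYALASSCGYGNWVRSCVLCCIKEVEIHQNKMFWWAEEKIVGGMIMWSAQSGKSCLKVCNVCEKNIMEITDAMHKK"
 },
 {
  "accession": "SIM_HOM_011.1",
  "coverage": 100.0,
  "percent_identity": 84.5,
  "protein_sequence": "TMRPRIFSMRTGTYMRSKTKVSMETPNRRMFVPLSLWGYWTASQVKPWWWDATYLPKCWLYADMNEMIQHSPENPWWHQIKTTGCYKDKVRQYGGSTGSNYCGDISNYFYSMAGQMRKHVNCYNFYAYASSCGVGNMVTSCVLCCRSEGGVHQNKPFWWTLEKIVTGMIMWSCWSGYCSLKVTNMCEAKIMWINDYMHKK"
 },
 {
  "accession": "SIM_HOM_012.1",
  "coverage": 100.0,
  "percent_identity": 79.0,
  "protein_sequence": "TMRDRNFSMRTGTWYRSKTCDSMATPFRYMIVPLELWGYWTESQVKPQWVDACYKPKCWLHAWMSCMIQHVPETPWWDQNKATICYKDWAPQGGGYTGHVYCFDISNKADSMDIQQRRDVNQTNFYALASTCGVGNMVRWCTLCCRVHGLVHENKPFWWHLEKIVTWTKMWSCQSGLHWLMVQNMCEKMIGNINPYMIKK"
 },
 {
  "accession": "SIM_HOM_013.1",
  "coverage": 100.0,
  "percent_identity": 78.5,
  "protein_sequence": "TMFDRNSSMITCCYMRGTLKVSMITPNYYFIVPLTLWVYWTHSQVKPWWWDACYKPKMWLHADRVEMIAHEPETFWWHQPKATICRKDKVRQGGGSTTHVYQGDISNKYDQMAGQMRMDVNCYNFYDLKSSCGVGNMVISCVLCCRKEGNEHRNKPFWWALEKIVYGMLMWSCKSGVCCLKMTCMQVKKIMNINDYQQKK"
 },
 {
  "accession": "SIM_HOM_014.1",
  "coverage": 100.0,
  "percent_identity": 83.5,
  "protein_sequence": "TMRNRNIGMRTGTRMRSKNKVSSETPNRYAIVPLELWSYWTHVSVKPWYWDACYKPKCWLHPDMSEMIQHVEETPWWHQNKATICNKDKVIQGGGSIGNVYCGHISNKFDSMATQMREDVNLYGFYALASSCGVGNMVYSCVLCDRLEGFVHQNKPFWWALEKGVTGMIMASCQSARCCLIVTWMCEKEAMNINDYMHKK"
 },
 {
  "accession": "SIM_HOM_015.1",
  "coverage": 100.0,
  "percent_identity": 81.5,
  "protein_sequence": "TMRGRNFVMRTGTVMREQTKVSMETPNRQMIVPLELWGYWTHVQVSPWCWDAIYKPKCWLHADMSEMIQHVPETPWYHQNKATICYKDKCRAGEGSTGHIYCGDISWKFMSMAGCMFRDVNQYNFYPLASPCGVGNRQCSCVLCCIVEYLVHQNKPSWWALEKIVTGMIMWICQSIRCKLKVTNFVGKKIMNINDYGHKE"
 },
 {
  "accession": "SIM_HOM_016.1",
  "coverage": 100.0,
  "percent_identity": 74.5,
  "protein_sequence": "GMRDRWFSMRTGTYIRSTTKVSHCDPNRYMISPLVLKGYWTVSQVKPWAWDLCYKPKCVLHTDESENIQHVPETPWEYQGKQTNQYRDKVRQDGGSFGHYYYTDISNKFDPMAGDCWRDVMYQGFYTLASSCGVGNMVRTNVLCLRVEGGVHQNKRFEWALTKIVTGMIRHSCQSDRCCLKVTNICETKIMWINDYMHKG"
 },
 {
  "accession": "SIM_HOM_017.1",
  "coverage": 100.0,
  "percent_identity": 71.5,
  "protein_sequence": "TPRARQMSMRTGTMKRHKTKVHQECPNYTLIVPLESWRYLVHSQVKRWWIDASYKPFCKLFADMSEMIQHVPETCWWHQCKPTIPYKCKVMQKVGSTFHVYCEDISLKFDSMAGQGRRDQNYAMFYFLAGSCGVGNMYRRCVLCCRTEGGVHQNKWFVWALESIVTGMHMWSCHSGRCDLNVTNMRLWKIMYIDDYMHKF"
 },
 {
  "accession": "SIM_HOM_018.1",
  "coverage": 100.0,
  "percent_identity": 82.0,
  "protein_sequence": "SMTDRNFSPRTGHYMRSKTKVMMETPNCYMIVPLELWGEHTHSQVKPWWWFRCYKPKCELHADMSEMIQHVPETSWWHQNSATICYKHHVCCGGTPTGHVYCGDIKNKIDSMAGVNRRDVGCVNFYHMASVCGVGNMVRSCVLCCRVEGGVHNNKKQWWALEKIVTGMTMWSKQSCRCCLKVTNMCESKIMNINDYMFKK"
 },
 {
  "accession": "SIM_HOM_019.1",
  "coverage": 100.0,
  "percent_identity": 77.5,
  "protein_sequence": "TMRDRNASMRTMTYIRSKTKVSMETMNRYMIVPLEYHGPWTHSQVKPWWWDACYKPPCWDHEDKSAMIQPVPETPLWFQNWATICYKDKGRQGGGSTRHVHCGDISSAFDSMANIMRRDVNCHFFYKLFDSHGVGNEWRSCVLNFEVEDACHQNKPFWWALEKIALGMIMQSCQSGRCCLKQTNMCEKKIMNIDKYGHKL"
 }
]
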
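# Per-species regional endemic-status fixture.
# Codes: E endemic, P present (non-endemic mark), NE near-endemic, - no mark.
# species_present: mpa_hotspot=53 mpa_knysna_province=60 greater_mpa_region=69 sea_dominion=70 study_area=73
family	species	mpa_hotspot	mpa_knysna_province	greater_mpa_region	sea_dominion	study_area
Bothriembryontidae	Prestonella bowkeri	-	-	-	E	E
Bothriembryontidae	Prestonella nuptialis	E	-	E	E	E
Rhytididae	Chlamydephorus bruggeni	E	E	E	E	E
Rhytididae	Chlamydephorus burnupi	P	P	E	E	E
Rhytididae	Chlamydephorus dimidius	E	E	E	E	E
Rhytididae	Chlamydephorus gibbonsi	E	E	E	E	E
Rhytididae	Chlamydephorus lawrencei	-	-	E	E	E
Rhytididae	Chlamydephorus parva	E	E	E	E	E
Rhytididae	Chlamydephorus purcelli	-	-	-	-	E
Rhytididae	Chlamydephorus sexangulus	-	E	E	E	E
Rhytididae	Chlamydephorus watsoni	E	E	E	E	E
Rhytididae	Afrorhytida burseyae	E	P	E	E	E
Rhytididae	Afrorhytida knysnaensis	E	-	E	E	E
Rhytididae	Afrorhytida kraussi	-	E	E	E	E
Rhytididae	Afrorhytida trimeni	E	E	E	E	E
Rhytididae	Capitina calcicola	-	-	-	-	E
Rhytididae	Capitina schaerfiae	-	E	E	E	E
Rhytididae	Nata aequiplicata	E	E	E	E	E
Rhytididae	Nata dumeticola	-	-	-	-	NE
Rhytididae	Nata tarachodes	-	-	-	-	E
Rhytididae	Nata vernicosa-erugata	-	-	-	-	E
Rhytididae	Nata watsoni	E	-	E	E	E
Rhytididae	Natalina beyrichi	E	E	E	E	E
Rhytididae	Natalina cafra	E	E	E	E	E
Rhytididae	Natalina inhluzana	E	E	E	E	E
Rhytididae	Natalina quekettiana	P	P	E	E	E
Rhytididae	Natalina reenenensis	E	E	E	E	E
Rhytididae	Natalina wesseliana	-	-	-	-	E
Rhytididae	Natella viridescens	P	P	P	E	E
Urocyclidae	Kerkophorus ampliatus	E	E	E	E	E
Urocyclidae	Kerkophorus bicolor	-	E	E	E	E
Urocyclidae	Kerkophorus cingulatus	-	E	E	E	E
Urocyclidae	Kerkophorus corneus	-	P	E	E	E
Urocyclidae	Kerkophorus inunctus	E	E	E	E	E
Urocyclidae	Kerkophorus knysnaensis	-	E	E	E	E
Urocyclidae	Kerkophorus melvilli	E	E	E	E	E
Urocyclidae	Kerkophorus perfragilis	-	P	E	E	E
Urocyclidae	Kerkophorus perlevis	-	E	E	E	E
Urocyclidae	Kerkophorus piperatus-vittarubra	-	P	E	E	E
Urocyclidae	Kerkophorus poeppigii	P	P	P	E	E
Urocyclidae	Kerkophorus pumilio	-	P	E	E	E
Urocyclidae	Kerkophorus puzeyi	E	E	E	E	E
Urocyclidae	Kerkophorus russofulgens	E	E	E	E	E
Urocyclidae	Kerkophorus scrobicolus	E	E	E	E	E
Urocyclidae	Kerkophorus terrestris	E	E	E	E	E
Urocyclidae	Kerkophorus vandenbroeckii	-	P	E	E	E
Urocyclidae	Kerkophorus vitalis	E	E	E	E	E
Urocyclidae	Kerkophorus zonamydrus	-	E	E	E	E
Urocyclidae	Microkerkus arnotti	-	-	-	-	E
Urocyclidae	Microkerkus burnupi	-	E	E	E	E
Urocyclidae	Microkerkus chrysoprasinus	P	P	E	E	E
Urocyclidae	Microkerkus fuscicolor	P	P	P	E	E
Urocyclidae	Microkerkus leucospira	E	E	E	E	E
Urocyclidae	Microkerkus maseruensis	P	P	E	E	E
Urocyclidae	Microkerkus pondoensis	E	E	E	E	E
Urocyclidae	Microkerkus sibaya	E	E	E	E	E
Urocyclidae	Microkerkus symmetricus	P	P	P	E	E
Urocyclidae	Microkerkus transvaalensis	-	P	E	E	E
Urocyclidae	Ptilototheca soutpansbergensis	-	P	E	E	E
Urocyclidae	Selatodryas luteosoma-roseosoma	E	P	E	E	E
Urocyclidae	Sheldonia aloicola	E	E	E	E	E
Urocyclidae	Sheldonia asthenes	-	-	E	E	E
Urocyclidae	Sheldonia caledonensis	-	-	-	-	E
Urocyclidae	Sheldonia capsula	-	-	-	-	E
Urocyclidae	Sheldonia cotyledonis	-	-	-	-	E
Urocyclidae	Sheldonia crawfordi	-	-	E	E	E
Urocyclidae	Sheldonia fingolandensis	E	E	E	E	E
Urocyclidae	Sheldonia hudsoniae	-	E	E	E	E
Urocyclidae	Sheldonia monsmaripi	E	E	E	E	E
Urocyclidae	Sheldonia natalensis	-	E	E	E	E
Urocyclidae	Sheldonia phytostylus	-	E	E	E	E
Urocyclidae	Sheldonia trotteriana	-	-	-	E	E
Urocyclidae	Sheldonia wolkbergensis	-	P	E	E	E
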
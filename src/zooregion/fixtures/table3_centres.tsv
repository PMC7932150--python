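# COE-restricted species with range descriptors and ledger overrides.
species	family	centre	centre_n_ogus	n_occupied	cone_restricted	area_fraction	override
Kerkophorus pumilio	Urocyclidae	Sky islands	2	1	1	0.25	
Ptilototheca soutpansbergensis	Urocyclidae	Sky islands	2	1	1	0.25	
Kerkophorus perfragilis	Urocyclidae	Sky islands	2	1	1	0.25	
Sheldonia wolkbergensis	Urocyclidae	Sky islands	2	1	1	0.25	
Chlamydephorus watsoni	Rhytididae	Extended Maputaland	4	4	0	0.7	
Sheldonia monsmaripi	Urocyclidae	Extended Maputaland	4	1	1	0.1	
Chlamydephorus bruggeni	Rhytididae	Extended Maputaland	4	1	1	0.1	
Microkerkus sibaya	Urocyclidae	Extended Maputaland	4	1	0	0.1	
Natalina inhluzana	Rhytididae	Natal	3	1	1	0.2	
Kerkophorus bicolor	Urocyclidae	Natal	3	1	1	0.2	
Microkerkus burnupi	Urocyclidae	Natal	3	1	1	0.2	
Kerkophorus ampliatus	Urocyclidae	Natal	3	2	1	0.3	
Kerkophorus melvilli	Urocyclidae	Natal	3	2	1	0.3	
Kerkophorus russofulgens	Urocyclidae	Natal	3	2	1	0.3	
Natalina beyrichi	Rhytididae	Extended Pondoland	2	2	0	0.7	
Kerkophorus vitalis	Urocyclidae	Extended Pondoland	2	2	0	0.7	
Microkerkus pondoensis	Urocyclidae	Extended Pondoland	2	2	0	0.3	
Kerkophorus puzeyi	Urocyclidae	Extended Pondoland	2	2	0	0.3	
Kerkophorus terrestris	Urocyclidae	Extended Pondoland	2	2	0	0.3	
Kerkophorus scrobicolus	Urocyclidae	Extended Pondoland	2	1	0	0.2	
Sheldonia fingolandensis	Urocyclidae	Extended Pondoland	2	1	0	0.2	
Afrorhytida kraussi	Rhytididae	Albany-Knysna	2	1	0	0.6	not_narrow
Sheldonia phytostylus	Urocyclidae	Albany-Knysna	2	1	0	0.6	not_narrow
Sheldonia aloicola	Urocyclidae	Albany-Knysna	2	2	0	0.8	
Sheldonia hudsoniae	Urocyclidae	Albany-Knysna	2	2	0	0.8	
Chlamydephorus parva	Rhytididae	Albany-Knysna	2	1	0	0.2	
Capitina schaerfiae	Rhytididae	Albany-Knysna	2	1	1	0.1	
Kerkophorus knysnaensis	Urocyclidae	Albany-Knysna	2	1	1	0.1	
Nata aequiplicata	Rhytididae	Albany-Knysna	2	1	1	0.2	not_narrow
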
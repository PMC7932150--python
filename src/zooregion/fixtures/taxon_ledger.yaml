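registry:
- species_id: Prestonella bowkeri
  genus: Prestonella
  family: Bothriembryontidae
- species_id: Prestonella nuptialis
  genus: Prestonella
  family: Bothriembryontidae
- species_id: Prestonella quadingensis
  genus: Prestonella
  family: Bothriembryontidae
- species_id: Chlamydephorus bruggeni
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus burnupi
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus dimidius
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus gibbonsi
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus lawrencei
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus parva
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus purcelli
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus sexangulus
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Chlamydephorus watsoni
  genus: Chlamydephorus
  family: Rhytididae
- species_id: Afrorhytida burseyae
  genus: Afrorhytida
  family: Rhytididae
- species_id: Afrorhytida knysnaensis
  genus: Afrorhytida
  family: Rhytididae
- species_id: Afrorhytida kraussi
  genus: Afrorhytida
  family: Rhytididae
- species_id: Afrorhytida trimeni
  genus: Afrorhytida
  family: Rhytididae
- species_id: Capitina calcicola
  genus: Capitina
  family: Rhytididae
- species_id: Capitina schaerfiae
  genus: Capitina
  family: Rhytididae
- species_id: Natalina beyrichi
  genus: Natalina
  family: Rhytididae
- species_id: Natalina cafra
  genus: Natalina
  family: Rhytididae
- species_id: Natalina inhluzana
  genus: Natalina
  family: Rhytididae
- species_id: Natalina quekettiana
  genus: Natalina
  family: Rhytididae
- species_id: Natalina reenenensis
  genus: Natalina
  family: Rhytididae
- species_id: Natalina wesseliana
  genus: Natalina
  family: Rhytididae
- species_id: Nata aequiplicata
  genus: Nata
  family: Rhytididae
- species_id: Nata dumeticola
  genus: Nata
  family: Rhytididae
- species_id: Nata erugata
  genus: Nata
  family: Rhytididae
- species_id: Nata tarachodes
  genus: Nata
  family: Rhytididae
- species_id: Nata vernicosa
  genus: Nata
  family: Rhytididae
- species_id: Nata watsoni
  genus: Nata
  family: Rhytididae
- species_id: Natella viridescens
  genus: Natella
  family: Rhytididae
- species_id: Kerkophorus ampliatus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus bicolor
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus cingulatus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus corneus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus inunctus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus knysnaensis
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus melvilli
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus perfragilis
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus perlevis
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus phaedimus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus piperatus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus poeppigii
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus pumilio
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus puzeyi
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus russofulgens
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus scrobicolus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus terrestris
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus vandenbroeckii
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus vitalis
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus vittarubra
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Kerkophorus zonamydrus
  genus: Kerkophorus
  family: Urocyclidae
- species_id: Microkerkus arnotti
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus burnupi
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus chrysoprasinus
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus fuscicolor
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus leucospira
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus maseruensis
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus pondoensis
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus sibaya
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus symmetricus
  genus: Microkerkus
  family: Urocyclidae
- species_id: Microkerkus transvaalensis
  genus: Microkerkus
  family: Urocyclidae
- species_id: Ptilototheca soutpansbergensis
  genus: Ptilototheca
  family: Urocyclidae
- species_id: Selatodryas luteosoma
  genus: Selatodryas
  family: Urocyclidae
- species_id: Selatodryas roseosoma
  genus: Selatodryas
  family: Urocyclidae
- species_id: Sheldonia aloicola
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia asthenes
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia caledonensis
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia capsula
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia cotyledonis
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia crawfordi
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia fingolandensis
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia hewitti
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia hudsoniae
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia monsmaripi
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia natalensis
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia phytostylus
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia trotteriana
  genus: Sheldonia
  family: Urocyclidae
- species_id: Sheldonia wolkbergensis
  genus: Sheldonia
  family: Urocyclidae
ledger:
  exclude:
  - Prestonella quadingensis
  synonymise:
  - junior: Sheldonia hewitti
    senior: Sheldonia aloicola
  - junior: Kerkophorus phaedimus
    senior: Kerkophorus corneus
  merge_complex:
  - members:
    - Nata vernicosa
    - Nata erugata
    name: Nata vernicosa-erugata
  - members:
    - Kerkophorus piperatus
    - Kerkophorus vittarubra
    name: Kerkophorus piperatus-vittarubra
  - members:
    - Selatodryas luteosoma
    - Selatodryas roseosoma
    name: Selatodryas luteosoma-roseosoma
  overrides:
    Prestonella nuptialis: narrow
    Afrorhytida trimeni: narrow
    Selatodryas luteosoma-roseosoma: narrow
    Afrorhytida kraussi: not_narrow
    Sheldonia phytostylus: not_narrow
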
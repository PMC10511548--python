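scenario_id,country,cancer,agent,gcsf_cost_per_cycle,drug_unit_price,fn_hospitalisation_cost,provenance,flag
austria_bc_filgrastim,Austria,BC,filgrastim,200.12253146631713,20.012253146631714,4570.806315336075,calibrated,
austria_bc_pegfilgrastim,Austria,BC,pegfilgrastim,264.7964886186324,264.7964886186324,4616.219050852635,calibrated,
austria_nsclc_filgrastim,Austria,NSCLC,filgrastim,192.40037264886007,19.240037264886006,7362.772616267439,calibrated,
austria_nsclc_pegfilgrastim,Austria,NSCLC,pegfilgrastim,262.5899999915779,262.5899999915779,7462.52993049962,calibrated,
austria_nhl_filgrastim,Austria,NHL,filgrastim,298.95202911277806,29.895202911277806,7513.826318614911,calibrated,
austria_nhl_pegfilgrastim,Austria,NHL,pegfilgrastim,394.75312258127576,394.75312258127576,7525.261627518124,calibrated,
france_bc_filgrastim,France,BC,filgrastim,219.88394692334182,21.988394692334182,6842.317936564543,calibrated,
france_bc_pegfilgrastim,France,BC,pegfilgrastim,349.46573238909644,349.46573238909644,6912.80183210403,calibrated,
france_nsclc_filgrastim,France,NSCLC,filgrastim,218.69683752933474,21.869683752933476,10601.45582415466,calibrated,
france_nsclc_pegfilgrastim,France,NSCLC,pegfilgrastim,349.08939274324865,349.08939274324865,10741.737545404416,calibrated,
france_nhl_filgrastim,France,NHL,filgrastim,371.7819464847273,37.17819464847273,9716.28715725763,calibrated,
france_nhl_pegfilgrastim,France,NHL,pegfilgrastim,524.6426221705522,524.6426221705522,9728.046606160653,calibrated,
germany_bc_filgrastim,Germany,BC,filgrastim,381.27066755695347,38.127066755695346,1690.7757987315129,calibrated,
germany_bc_pegfilgrastim,Germany,BC,pegfilgrastim,671.1651450608181,671.1651450608181,1641.3501443877028,calibrated,
germany_nsclc_filgrastim,Germany,NSCLC,filgrastim,372.065446213095,37.206544621309504,3581.709448492995,calibrated,
germany_nsclc_pegfilgrastim,Germany,NSCLC,pegfilgrastim,670.5527590016939,670.5527590016939,3562.362091645384,calibrated,
germany_nhl_filgrastim,Germany,NHL,filgrastim,576.1358118149968,57.61358118149968,4859.535428603224,calibrated,
germany_nhl_pegfilgrastim,Germany,NHL,pegfilgrastim,1005.5895421304538,1005.5895421304538,4792.424787054119,calibrated,
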
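model_name,region_id,module_label
one_module,Fr,all
one_module,Pa,all
one_module,NPM_d,all
one_module,NPM_p,all
one_module,Max_l,all
one_module,Max_i,all
one_module,Max_p,all
one_module,Occ,all
one_module,Co,all
one_module,Qu,all
one_module,JJ,all
one_module,Sq,all
one_module,BS,all
one_module,Vo,all
one_module,Pt,all
one_module,St,all
two_anterior_posterior,Fr,anterior
two_anterior_posterior,Pa,posterior
two_anterior_posterior,NPM_d,anterior
two_anterior_posterior,NPM_p,anterior
two_anterior_posterior,Max_l,anterior
two_anterior_posterior,Max_i,anterior
two_anterior_posterior,Max_p,anterior
two_anterior_posterior,Occ,posterior
two_anterior_posterior,Co,posterior
two_anterior_posterior,Qu,posterior
two_anterior_posterior,JJ,posterior
two_anterior_posterior,Sq,posterior
two_anterior_posterior,BS,posterior
two_anterior_posterior,Vo,anterior
two_anterior_posterior,Pt,posterior
two_anterior_posterior,St,posterior
two_dorsal_ventral,Fr,dorsal
two_dorsal_ventral,Pa,dorsal
two_dorsal_ventral,NPM_d,dorsal
two_dorsal_ventral,NPM_p,ventral
two_dorsal_ventral,Max_l,ventral
two_dorsal_ventral,Max_i,ventral
two_dorsal_ventral,Max_p,ventral
two_dorsal_ventral,Occ,dorsal
two_dorsal_ventral,Co,ventral
two_dorsal_ventral,Qu,dorsal
two_dorsal_ventral,JJ,dorsal
two_dorsal_ventral,Sq,dorsal
two_dorsal_ventral,BS,ventral
two_dorsal_ventral,Vo,ventral
two_dorsal_ventral,Pt,ventral
two_dorsal_ventral,St,dorsal
two_medial_lateral,Fr,medial
two_medial_lateral,Pa,medial
two_medial_lateral,NPM_d,medial
two_medial_lateral,NPM_p,medial
two_medial_lateral,Max_l,lateral
two_medial_lateral,Max_i,lateral
two_medial_lateral,Max_p,lateral
two_medial_lateral,Occ,medial
two_medial_lateral,Co,medial
two_medial_lateral,Qu,lateral
two_medial_lateral,JJ,lateral
two_medial_lateral,Sq,lateral
two_medial_lateral,BS,medial
two_medial_lateral,Vo,medial
two_medial_lateral,Pt,lateral
two_medial_lateral,St,lateral
two_snout_rest,Fr,rest
two_snout_rest,Pa,rest
two_snout_rest,NPM_d,snout
two_snout_rest,NPM_p,snout
two_snout_rest,Max_l,snout
two_snout_rest,Max_i,snout
two_snout_rest,Max_p,snout
two_snout_rest,Occ,rest
two_snout_rest,Co,rest
two_snout_rest,Qu,rest
two_snout_rest,JJ,rest
two_snout_rest,Sq,rest
two_snout_rest,BS,rest
two_snout_rest,Vo,rest
two_snout_rest,Pt,rest
two_snout_rest,St,rest
two_cheek_snout_rest,Fr,rest
two_cheek_snout_rest,Pa,rest
two_cheek_snout_rest,NPM_d,cheek_snout
two_cheek_snout_rest,NPM_p,cheek_snout
two_cheek_snout_rest,Max_l,cheek_snout
two_cheek_snout_rest,Max_i,cheek_snout
two_cheek_snout_rest,Max_p,cheek_snout
two_cheek_snout_rest,Occ,rest
two_cheek_snout_rest,Co,rest
two_cheek_snout_rest,Qu,cheek_snout
two_cheek_snout_rest,JJ,cheek_snout
two_cheek_snout_rest,Sq,cheek_snout
two_cheek_snout_rest,BS,rest
two_cheek_snout_rest,Vo,rest
two_cheek_snout_rest,Pt,cheek_snout
two_cheek_snout_rest,St,rest
two_cheek_braincase_rest,Fr,cheek_braincase
two_cheek_braincase_rest,Pa,cheek_braincase
two_cheek_braincase_rest,NPM_d,rest
two_cheek_braincase_rest,NPM_p,rest
two_cheek_braincase_rest,Max_l,rest
two_cheek_braincase_rest,Max_i,rest
two_cheek_braincase_rest,Max_p,rest
two_cheek_braincase_rest,Occ,cheek_braincase
two_cheek_braincase_rest,Co,cheek_braincase
two_cheek_braincase_rest,Qu,cheek_braincase
two_cheek_braincase_rest,JJ,cheek_braincase
two_cheek_braincase_rest,Sq,cheek_braincase
two_cheek_braincase_rest,BS,cheek_braincase
two_cheek_braincase_rest,Vo,rest
two_cheek_braincase_rest,Pt,cheek_braincase
two_cheek_braincase_rest,St,cheek_braincase
three_cheek_snout_rest,Fr,rest
three_cheek_snout_rest,Pa,rest
three_cheek_snout_rest,NPM_d,snout
three_cheek_snout_rest,NPM_p,snout
three_cheek_snout_rest,Max_l,snout
three_cheek_snout_rest,Max_i,snout
three_cheek_snout_rest,Max_p,snout
three_cheek_snout_rest,Occ,rest
three_cheek_snout_rest,Co,rest
three_cheek_snout_rest,Qu,cheek
three_cheek_snout_rest,JJ,cheek
three_cheek_snout_rest,Sq,cheek
three_cheek_snout_rest,BS,rest
three_cheek_snout_rest,Vo,rest
three_cheek_snout_rest,Pt,cheek
three_cheek_snout_rest,St,rest
six_module,Fr,vault
six_module,Pa,vault
six_module,NPM_d,oral_nasal
six_module,NPM_p,oral_nasal
six_module,Max_l,face
six_module,Max_i,palate
six_module,Max_p,palate
six_module,Occ,base
six_module,Co,base
six_module,Qu,cheek
six_module,JJ,cheek
six_module,Sq,cheek
six_module,BS,base
six_module,Vo,palate
six_module,Pt,cheek
six_module,St,base
seven_module,Fr,vault
seven_module,Pa,vault
seven_module,NPM_d,oral_nasal
seven_module,NPM_p,oral_nasal
seven_module,Max_l,face
seven_module,Max_i,palate
seven_module,Max_p,palate
seven_module,Occ,base
seven_module,Co,base
seven_module,Qu,quadrate
seven_module,JJ,quadrate
seven_module,Sq,squamosal_pterygoid
seven_module,BS,base
seven_module,Vo,palate
seven_module,Pt,squamosal_pterygoid
seven_module,St,base
eight_module,Fr,vault
eight_module,Pa,vault
eight_module,NPM_d,oral_nasal
eight_module,NPM_p,oral_nasal
eight_module,Max_l,face
eight_module,Max_i,palate
eight_module,Max_p,palate
eight_module,Occ,occipital
eight_module,Co,occipital
eight_module,Qu,quadrate
eight_module,JJ,quadrate
eight_module,Sq,squamosal_pterygoid
eight_module,BS,base
eight_module,Vo,palate
eight_module,Pt,squamosal_pterygoid
eight_module,St,base
ten_module,Fr,frontal
ten_module,Pa,parietal
ten_module,NPM_d,npm_dorsal
ten_module,NPM_p,npm_palatal
ten_module,Max_l,maxillopalatine
ten_module,Max_i,maxillopalatine
ten_module,Max_p,maxillopalatine
ten_module,Occ,occipital
ten_module,Co,occipital
ten_module,Qu,cheek
ten_module,JJ,cheek
ten_module,Sq,cheek
ten_module,BS,basale_vomer
ten_module,Vo,basale_vomer
ten_module,Pt,pterygoid
ten_module,St,stapes
twelve_module,Fr,frontal
twelve_module,Pa,parietal
twelve_module,NPM_d,npm_dorsal
twelve_module,NPM_p,npm_palatal
twelve_module,Max_l,max_lateral
twelve_module,Max_i,max_palate
twelve_module,Max_p,max_palate
twelve_module,Occ,occipital
twelve_module,Co,occipital
twelve_module,Qu,quadrate
twelve_module,JJ,quadrate
twelve_module,Sq,squamosal
twelve_module,BS,basale_vomer
twelve_module,Vo,basale_vomer
twelve_module,Pt,pterygoid
twelve_module,St,stapes
fourteen_module,Fr,frontal
fourteen_module,Pa,parietal
fourteen_module,NPM_d,npm_dorsal
fourteen_module,NPM_p,npm_palatal
fourteen_module,Max_l,max_lateral
fourteen_module,Max_i,max_inter
fourteen_module,Max_p,max_palate
fourteen_module,Occ,occipital
fourteen_module,Co,occipital
fourteen_module,Qu,quadrate
fourteen_module,JJ,quadrate
fourteen_module,Sq,squamosal
fourteen_module,BS,basale
fourteen_module,Vo,vomer
fourteen_module,Pt,pterygoid
fourteen_module,St,stapes
sixteen_module,Fr,Fr
sixteen_module,Pa,Pa
sixteen_module,NPM_d,NPM_d
sixteen_module,NPM_p,NPM_p
sixteen_module,Max_l,Max_l
sixteen_module,Max_i,Max_i
sixteen_module,Max_p,Max_p
sixteen_module,Occ,Occ
sixteen_module,Co,Co
sixteen_module,Qu,Qu
sixteen_module,JJ,JJ
sixteen_module,Sq,Sq
sixteen_module,BS,BS
sixteen_module,Vo,Vo
sixteen_module,Pt,Pt
sixteen_module,St,St
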
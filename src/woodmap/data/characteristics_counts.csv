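characteristic,level,wood_fuel,count
property_type,detached,False,2890474
property_type,flat,False,5308610
property_type,house_form_missing,False,53891
property_type,other,False,9772
property_type,semi_detached,False,4295286
property_type,terrace,False,4781685
property_type,detached,True,679637
property_type,flat,True,26946
property_type,house_form_missing,True,2781
property_type,other,True,215
property_type,semi_detached,True,377068
property_type,terrace,True,282155
tenure,new_build,False,738240
tenure,owner_occupied,False,8707524
tenure,rented_private,False,3299967
tenure,rented_social,False,3143415
tenure,,False,1450572
tenure,new_build,True,18278
tenure,owner_occupied,True,1105820
tenure,rented_private,True,165375
tenure,rented_social,True,18706
tenure,,True,60623
sca,no,False,8427370
sca,yes,False,8912348
sca,no,True,1159221
sca,yes,True,209581
urban,no,False,2455205
urban,yes,False,14093037
urban,,False,791476
urban,no,True,746353
urban,yes,True,594822
urban,,True,27627
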
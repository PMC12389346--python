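name,display_name,smiles,mw,logp,rb,ps,hbd,hba,ar,mc_printed,msc_printed,functional_roles,solid_form,shelf_life_years
cellulose,Cellulose,OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O,342.30,-5.40,4,190.00,8,11,0,22,10,adsorbent;disintegrant;binder;diluent,crystalline,4
hpmc,HPMC,COCC1OC(OC)C(OCC(C)O)C(OC)C1OC,1261.40,-2.32,30,365.00,8,30,0,50,20,dispersing;solubilizing;stabilizing;thickening;film-coating;binder,amorphous,3
lactose,Lactose,OCC1OC(OC2C(CO)OC(O)C(O)C2O)C(O)C(O)C1O,360.31,-5.73,4,191.00,9,12,0,22,12,binder;filler;diluent,mixed,3
mannitol,Mannitol,OCC(O)C(O)C(O)C(O)CO,182.17,-3.73,2,131.38,6,6,0,21,9,diluent;plasticizer,crystalline,5
silica,Silica,O=[Si]=O,60.84,-0.62,0,34.10,2,0,0,23,4,adsorbent;disintegrant;thermal stabilizer,amorphous,5
sucrose,Sucrose,OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O,342.30,-4.53,5,189.55,8,11,0,40,10,binder;filler,crystalline,5
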
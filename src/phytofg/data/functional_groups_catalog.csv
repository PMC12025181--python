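code,habitat,representative_taxa,tolerance,susceptibility,dominant_in_study
A,"Oligotrophic, clean, deep water",Rhizosolenia sp.,Low nutrients,Elevated pH,0
B,"Mesotrophic trophic, small-to-medium, or large shallow-water bodies",Cyclotella sp.,Low light,"Elevated pH, water stratification",1
C,"Eutrophic, small- and medium-sized reservoirs",Asterionella sp.,Low light,Water stratification,0
D,"Rich in nutrients, cloudy",Synedra sp.;Nitzschia sp.,Scouring,Nutrient deficiency,1
E,"Oligotrophic or heterotrophic type, small water bodies, shallow water",Dinobryon divergens,Low nutrients,CO2 deficiency,0
F,"Mesotrophic-to-eutrophic, clean, and strong water mixing",Oocystis sp.;Kirchneriella sp.,Low nutrients,CO2 deficiency,0
G,"Eutrophic, stagnant water bodies",Eudorina sp.;Pandorina sp.,High light,Nutrient salt deficiency,0
H1,"Eutrophic, stratified, low nitrogen content",Anabaena sp.;Aphanizomenon sp.,Low carbon/nitrogen content,"Water mixing, low light, low phosphorus",0
J,"High nutrient, mixed, shallow water",Scenedesmus sp.;Crucigenia sp.;Tetraedron sp.,,High light,0
K,"Eutrophic, shallow water",Aphanocapsa sp.,,Strong water mixing,0
L_M,"Eutrophic to hypereutrophic, small- and medium-sized water bodies",Dactylococcopsis sp.;Ceratium sp.,Extremely low carbon content,"Water mixing, low light",0
L_O,"Mesotrophic-to-eutrophic, medium-to-large water bodies, can be deep or shallow",Merismopedia sp.;Chroococcus sp.;Peridinium sp.,Nutrient stratification,Prolonged/deep mixing,1
MP,"Frequent agitation, turbidity, shallow water",Oscillatoria sp.;Navicula sp.;Achnanthes sp.,Mixing disturbance,,0
N,Continuous or semi-continuous mixed bodies of water,Cosmarium sp.,Low nutrients,"Water stratification, elevated pH",0
P,"It is similar to functional group N, but the trophic status of the water body is higher",Melosira sp.;Fragilaria sp.;Closterium sp.,"Low light, low carbon content","Water stratification, silicon deficiency",1
S1,The mixture is cloudy and has low transparency,Pseudanabaena limnetica;Rhabdogloea sp.;Limnothrix sp.,Extremely low light,Scouring,1
S2,"Warm, highly alkaline, shallow water",Spirulina sp.,Low light,Scouring,0
S_N,"Warm, blended",Cylindrospermum raciborskii;Raphidiopsis sp.,"Low light, low nutrients",Scouring,0
T,Mix water bodies continuously,Mougeotia sp.;Quadrigula chodatii,Low light,Nutrient deficiency,0
TC,"Eutrophication, still or flowing water, with upright plants",Lyngbya sp.,,Scouring,0
W1,"Organic pollution, shallow water",Euglena sp.;Euglena oxyuris,High biochemical oxygen demand (BOD),Grazing pressure,1
W2,"Mesotrophic nutrition, shallow water",Trachelomonas sp.,,,1
X1,"Super nutritious, shallow water",Chlorella sp.;Ankistrodesmus sp.,Water stratification,"Nutrient deficiency, filter feeding",0
X2,"Mesotrophic-to-eutrophic, shallow water",Chlamydomonas sp.,Water stratification,"Water mixing, filter feeding",0
X3,"Oligotrophic, mixed, shallow water",Schroederia sp.,Harsh environmental conditions,"Water mixing, grazing pressure",0
Y,Still-water environment,Cryptomonas sp.;Gymnodinium sp.,Low light,Predation,1
Z,Oligotrophic,Synechococcus sp.,Low nutrients,"Low light, grazing pressure",0
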
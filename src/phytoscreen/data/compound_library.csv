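name,formula,compound_class,intrinsic_cation,rt_min,source_botanical
arginine,C6H14N4O2,amino_acid,0,0.8,
betaine,C5H11NO2,amino_acid,0,1.1,
adenosine,C10H13N5O4,nucleoside,0,1.6,
proline,C5H9NO2,amino_acid,0,2.0,
tyrosine,C9H11NO3,amino_acid,0,2.4,
phenylalanine,C9H11NO2,amino_acid,0,2.9,
tryptophan,C11H12N2O2,amino_acid,0,3.4,
gallic_acid,C7H6O5,phenolic_acid,0,3.8,
rehmannioside_D,C27H42O20,iridoid,0,4.2,Rehmannia glutinosa
geniposidic_acid,C16H22O10,iridoid,0,4.7,Plantago asiatica
neochlorogenic_acid,C16H18O9,quinic_acid_derivative,0,5.1,
magnocurarine,C19H24NO3,benzylisoquinoline,1,5.5,
phellodendrine,C20H24NO4,tetrahydroprotoberberine,1,6.0,Phellodendron chinense
magnoflorine,C20H24NO4,aporphine,1,6.4,
cianidanol,C15H14O6,flavanol,0,6.9,
procyanidin_B1,C30H26O12,flavanol,0,7.3,
chlorogenic_acid,C16H18O9,quinic_acid_derivative,0,7.8,
cryptochlorogenic_acid,C16H18O9,quinic_acid_derivative,0,8.3,
caffeic_acid,C9H8O4,phenolic_acid,0,8.8,
epicatechin,C15H14O6,flavanol,0,9.3,
yuanhunine,C21H25NO4,tetrahydroprotoberberine,0,9.8,
echinacoside,C35H46O20,phenylethanoid_glycoside,0,10.3,Cistanche deserticola
daidzin,C21H20O9,isoflavone,0,10.8,Psoralea corylifolia
columbamine,C20H20NO4,protoberberine,1,11.3,
jateorhizine,C20H20NO4,protoberberine,1,11.8,
beta_ecdysterone,C27H44O7,steroid,0,12.3,Achyranthes bidentata
ferulic_acid,C10H10O4,phenolic_acid,0,12.8,
epiberberine,C20H18NO4,protoberberine,1,13.3,
coptisine,C19H14NO4,protoberberine,1,13.8,
berberine,C20H18NO4,protoberberine,1,14.3,Phellodendron chinense
berberrubine,C19H15NO4,protoberberine,0,14.8,
tubuloside_A,C37H48O21,phenylethanoid_glycoside,0,15.3,
acteoside,C29H36O15,phenylethanoid_glycoside,0,15.8,
tetrahydroxystilbene_glucoside,C20H22O9,stilbene,0,16.3,Polygonum multiflorum
hyperoside,C21H20O12,flavonol,0,16.8,
isoquercetin,C21H20O12,flavonol,0,17.3,
rutin,C27H30O16,flavonol,0,17.8,
astragalin,C21H20O11,flavonol,0,18.3,
cosmosiin,C21H20O10,flavone,0,18.8,
quercitrin,C21H20O11,flavonol,0,19.3,
ginsenoside_Rg1,C42H72O14,triterpenoid_saponin,0,19.8,Panax ginseng
ginsenoside_Re,C48H82O18,triterpenoid_saponin,0,20.3,Panax ginseng
1_5_dicaffeoylquinic_acid,C25H24O12,quinic_acid_derivative,0,20.8,
eriodictyol,C15H12O6,flavanone,0,21.3,
angelicin,C11H6O3,coumarin,0,21.8,Psoralea corylifolia
psoralen,C11H6O3,coumarin,0,22.3,Psoralea corylifolia
rutaevine,C26H30O9,triterpenoid,0,22.8,
luteolin,C15H10O6,flavone,0,23.3,
daidzein,C15H10O4,isoflavone,0,23.8,
quercetin,C15H10O7,flavonol,0,24.3,
azelaic_acid,C9H16O4,aliphatic_acid,0,24.8,
ginsenoside_Rb1,C54H92O23,triterpenoid_saponin,0,25.3,Panax ginseng
calycosin,C16H12O5,isoflavone,0,25.8,
baicalein,C15H10O5,flavone,0,26.3,
naringenin,C15H12O5,flavanone,0,26.8,
apigenin,C15H10O5,flavone,0,27.3,
genistein,C15H10O5,isoflavone,0,27.8,
chikusetsusaponin_IVa,C47H74O18,triterpenoid_saponin,0,28.3,
kaempferol,C15H10O6,flavonol,0,28.8,
limonin,C26H30O8,triterpenoid,0,29.3,
schisandrol_A,C24H32O7,lignan,0,29.8,Schisandra chinensis
wogonin,C16H12O5,flavone,0,30.3,
aloe_emodin,C15H10O5,anthraquinone,0,30.8,Polygonum multiflorum
emodin,C15H10O5,anthraquinone,0,31.3,Polygonum multiflorum
physcion,C16H12O5,anthraquinone,0,31.8,Polygonum multiflorum
gomisin_J,C22H28O6,lignan,0,32.3,Schisandra chinensis
schizandrin_A,C24H32O6,lignan,0,32.8,Schisandra chinensis
schisandrin_B,C23H28O6,lignan,0,33.3,Schisandra chinensis
ligustilide,C12H14O2,phthalide,0,33.8,Angelica sinensis
levistilide_A,C24H28O4,phthalide,0,34.3,Angelica sinensis
oleanolic_acid,C30H48O3,triterpenoid,0,34.8,
palmitic_acid,C16H32O2,aliphatic_acid,0,35.3,
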
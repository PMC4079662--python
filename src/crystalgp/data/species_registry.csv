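name,kind,charge,hofmeister_rank,peg_mass
ammonium,cation,1,1,
cesium,cation,1,2,
rubidium,cation,1,3,
potassium,cation,1,4,
lithium,cation,1,5,
sodium,cation,1,6,
barium,cation,2,7,
magnesium,cation,2,8,
manganese,cation,2,9,
zinc,cation,2,10,
cadmium,cation,2,11,
calcium,cation,2,12,
cobalt,cation,2,13,
copper,cation,2,14,
nickel,cation,2,15,
strontium,cation,2,16,
iron,cation,3,17,
gadolinium,cation,3,18,
samarium,cation,3,19,
citrate,anion,-3,9,
malonate,anion,-2,11,
succinate,anion,-2,8,
tartrate,anion,-2,4,
acetate,anion,-1,10,
bromide,anion,-1,15,
cacodylate,anion,-1,,
carbonate,anion,-2,5,
chloride,anion,-1,14,
citrate tribasic,anion,-3,2,
fluoride,anion,-1,12,
formate,anion,-1,13,
iodide,anion,-1,16,
molybdate,anion,-2,,
nitrate,anion,-1,,
phosphate monobasic,anion,-1,17,
phosphate dibasic,anion,-2,7,
phosphate tribasic,anion,-3,1,
pyrophosphate tetrabasic,anion,-4,,
sulfate,anion,-2,3,
tetraborate,anion,-2,,
thiocyanate,anion,-1,18,
thiosulfate,anion,-2,6,
4-aminosalicylate,anion,-1,,
PEG 200,PEG,0,,200
PEG 400,PEG,0,,400
PEG 550,PEG,0,,550
PEG 1000,PEG,0,,1000
PEG 1500,PEG,0,,1500
PEG 2000,PEG,0,,2000
PEG 3350,PEG,0,,3350
PEG 4000,PEG,0,,4000
PEG 5000,PEG,0,,5000
PEG 6000,PEG,0,,6000
PEG 8000,PEG,0,,8000
PEG 10000,PEG,0,,10000
PEG 20000,PEG,0,,20000
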
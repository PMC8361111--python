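name	kind	formula	monoisotopic_mass	nominal_mass
pelargonidin	core	C15H11O5	271.0601	271
cyanidin	core	C15H11O6	287.0550	287
peonidin	core	C16H13O6	301.0707	301
delphinidin	core	C15H11O7	303.0499	303
petunidin	core	C16H13O7	317.0656	317
malvidin	core	C17H15O7	331.0812	331
rosinidin	core	C17H15O6	315.0863	315
capensinidin	core	C18H17O7	345.0969	345
hexose	glycosyl	C6H10O5	162.0528	162
deoxyhexose	glycosyl	C6H10O4	146.0579	146
pentose	glycosyl	C5H8O4	132.0423	132
caffeoyl	acyl	C9H6O3	162.0317	162
feruloyl	acyl	C10H8O3	176.0473	176
p-hydroxybenzoyl	acyl	C7H4O2	120.0211	120
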
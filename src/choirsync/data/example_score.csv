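voice,piece,event_index,midi_pitch,onset_beats,duration_beats
soprano,Exemplum,0,67.0,0.0,2.0
soprano,Exemplum,1,69.0,2.0,0.5
soprano,Exemplum,2,68.0,2.5,1.0
soprano,Exemplum,3,69.0,3.5,1.0
soprano,Exemplum,4,70.0,4.5,1.0
soprano,Exemplum,5,69.0,5.5,1.0
soprano,Exemplum,6,68.0,6.5,1.0
soprano,Exemplum,7,67.0,7.5,2.0
soprano,Exemplum,8,69.0,9.5,2.0
soprano,Exemplum,9,67.0,11.5,1.0
soprano,Exemplum,10,65.0,12.5,1.0
soprano,Exemplum,11,67.0,13.5,1.0
soprano,Exemplum,12,65.0,14.5,2.0
soprano,Exemplum,13,64.0,16.5,2.0
soprano,Exemplum,14,66.0,18.5,1.0
soprano,Exemplum,15,65.0,19.5,2.0
soprano,Exemplum,16,67.0,21.5,1.0
soprano,Exemplum,17,69.0,22.5,0.5
soprano,Exemplum,18,68.0,23.0,1.0
soprano,Exemplum,19,70.0,24.0,0.5
soprano,Exemplum,20,68.0,24.5,0.5
soprano,Exemplum,21,70.0,25.0,0.5
soprano,Exemplum,22,72.0,25.5,0.5
soprano,Exemplum,23,70.0,26.0,1.0
soprano,Exemplum,24,72.0,27.0,1.0
soprano,Exemplum,25,68.0,28.0,1.0
soprano,Exemplum,26,69.0,29.0,0.5
soprano,Exemplum,27,70.0,29.5,1.0
soprano,Exemplum,28,69.0,30.5,1.0
soprano,Exemplum,29,71.0,31.5,2.0
soprano,Exemplum,30,73.0,33.5,2.0
soprano,Exemplum,31,69.0,35.5,1.0
soprano,Exemplum,32,68.0,36.5,0.5
soprano,Exemplum,33,72.0,37.0,2.0
soprano,Exemplum,34,71.0,39.0,1.0
soprano,Exemplum,35,69.0,40.0,1.0
soprano,Exemplum,36,69.0,41.0,2.0
soprano,Exemplum,37,70.0,43.0,1.0
soprano,Exemplum,38,69.0,44.0,0.5
soprano,Exemplum,39,70.0,44.5,1.0
soprano,Exemplum,40,72.0,45.5,0.5
soprano,Exemplum,41,72.0,46.0,2.0
soprano,Exemplum,42,68.0,48.0,1.0
soprano,Exemplum,43,67.0,49.0,0.5
soprano,Exemplum,44,65.0,49.5,2.0
soprano,Exemplum,45,66.0,51.5,1.0
soprano,Exemplum,46,65.0,52.5,1.0
soprano,Exemplum,47,67.0,53.5,0.5
soprano,Exemplum,48,65.0,54.0,2.0
soprano,Exemplum,49,67.0,56.0,0.5
soprano,Exemplum,50,63.0,56.5,0.5
soprano,Exemplum,51,62.0,57.0,0.5
soprano,Exemplum,52,60.0,57.5,2.0
soprano,Exemplum,53,62.0,59.5,1.0
soprano,Exemplum,54,60.0,60.5,0.5
soprano,Exemplum,55,62.0,61.0,1.0
soprano,Exemplum,56,64.0,62.0,1.0
soprano,Exemplum,57,65.0,63.0,0.5
soprano,Exemplum,58,64.0,63.5,1.0
soprano,Exemplum,59,62.0,64.5,1.0
altus,Exemplum,0,65.0,0.0,1.0
altus,Exemplum,1,61.0,1.0,0.5
altus,Exemplum,2,60.0,1.5,1.0
altus,Exemplum,3,62.0,2.5,1.0
altus,Exemplum,4,63.0,3.5,1.0
altus,Exemplum,5,61.0,4.5,0.5
altus,Exemplum,6,59.0,5.0,0.5
altus,Exemplum,7,55.0,5.5,1.0
altus,Exemplum,8,59.0,6.5,2.0
altus,Exemplum,9,57.0,8.5,2.0
altus,Exemplum,10,56.0,10.5,1.0
altus,Exemplum,11,58.0,11.5,2.0
altus,Exemplum,12,56.0,13.5,0.5
altus,Exemplum,13,55.0,14.0,0.5
altus,Exemplum,14,55.0,14.5,1.0
altus,Exemplum,15,55.0,15.5,1.0
altus,Exemplum,16,56.0,16.5,1.0
altus,Exemplum,17,55.0,17.5,2.0
altus,Exemplum,18,55.0,19.5,1.0
altus,Exemplum,19,55.0,20.5,2.0
altus,Exemplum,20,57.0,22.5,1.0
altus,Exemplum,21,58.0,23.5,2.0
altus,Exemplum,22,57.0,25.5,2.0
altus,Exemplum,23,55.0,27.5,1.0
altus,Exemplum,24,55.0,28.5,1.0
altus,Exemplum,25,55.0,29.5,2.0
altus,Exemplum,26,55.0,31.5,1.0
altus,Exemplum,27,55.0,32.5,1.0
altus,Exemplum,28,55.0,33.5,2.0
altus,Exemplum,29,57.0,35.5,0.5
altus,Exemplum,30,59.0,36.0,1.0
altus,Exemplum,31,61.0,37.0,2.0
altus,Exemplum,32,62.0,39.0,1.0
altus,Exemplum,33,63.0,40.0,0.5
altus,Exemplum,34,62.0,40.5,0.5
altus,Exemplum,35,64.0,41.0,2.0
altus,Exemplum,36,66.0,43.0,1.0
altus,Exemplum,37,66.0,44.0,2.0
altus,Exemplum,38,67.0,46.0,0.5
altus,Exemplum,39,68.0,46.5,1.0
altus,Exemplum,40,70.0,47.5,1.0
altus,Exemplum,41,74.0,48.5,1.0
altus,Exemplum,42,73.0,49.5,2.0
altus,Exemplum,43,74.0,51.5,1.0
altus,Exemplum,44,72.0,52.5,2.0
altus,Exemplum,45,71.0,54.5,2.0
altus,Exemplum,46,71.0,56.5,1.0
altus,Exemplum,47,69.0,57.5,2.0
altus,Exemplum,48,69.0,59.5,2.0
altus,Exemplum,49,69.0,61.5,2.0
altus,Exemplum,50,67.0,63.5,2.0
altus,Exemplum,51,69.0,65.5,1.0
altus,Exemplum,52,68.0,66.5,1.0
altus,Exemplum,53,69.0,67.5,1.0
altus,Exemplum,54,68.0,68.5,1.0
altus,Exemplum,55,70.0,69.5,2.0
altus,Exemplum,56,68.0,71.5,2.0
altus,Exemplum,57,67.0,73.5,2.0
altus,Exemplum,58,71.0,75.5,1.0
altus,Exemplum,59,73.0,76.5,1.0
tenor,Exemplum,0,64.0,0.0,2.0
tenor,Exemplum,1,62.0,2.0,1.0
tenor,Exemplum,2,58.0,3.0,0.5
tenor,Exemplum,3,56.0,3.5,1.0
tenor,Exemplum,4,58.0,4.5,2.0
tenor,Exemplum,5,54.0,6.5,1.0
tenor,Exemplum,6,54.0,7.5,1.0
tenor,Exemplum,7,52.0,8.5,1.0
tenor,Exemplum,8,53.0,9.5,0.5
tenor,Exemplum,9,51.0,10.0,2.0
tenor,Exemplum,10,52.0,12.0,1.0
tenor,Exemplum,11,50.0,13.0,1.0
tenor,Exemplum,12,52.0,14.0,1.0
tenor,Exemplum,13,50.0,15.0,2.0
tenor,Exemplum,14,50.0,17.0,1.0
tenor,Exemplum,15,54.0,18.0,0.5
tenor,Exemplum,16,52.0,18.5,0.5
tenor,Exemplum,17,51.0,19.0,2.0
tenor,Exemplum,18,53.0,21.0,0.5
tenor,Exemplum,19,54.0,21.5,1.0
tenor,Exemplum,20,50.0,22.5,1.0
tenor,Exemplum,21,51.0,23.5,2.0
tenor,Exemplum,22,52.0,25.5,2.0
tenor,Exemplum,23,53.0,27.5,2.0
tenor,Exemplum,24,51.0,29.5,0.5
tenor,Exemplum,25,50.0,30.0,1.0
tenor,Exemplum,26,50.0,31.0,0.5
tenor,Exemplum,27,50.0,31.5,2.0
tenor,Exemplum,28,50.0,33.5,0.5
tenor,Exemplum,29,51.0,34.0,0.5
tenor,Exemplum,30,52.0,34.5,1.0
tenor,Exemplum,31,54.0,35.5,1.0
tenor,Exemplum,32,52.0,36.5,1.0
tenor,Exemplum,33,54.0,37.5,1.0
tenor,Exemplum,34,55.0,38.5,0.5
tenor,Exemplum,35,54.0,39.0,2.0
tenor,Exemplum,36,52.0,41.0,2.0
tenor,Exemplum,37,54.0,43.0,1.0
tenor,Exemplum,38,55.0,44.0,1.0
tenor,Exemplum,39,57.0,45.0,1.0
tenor,Exemplum,40,55.0,46.0,1.0
tenor,Exemplum,41,55.0,47.0,2.0
tenor,Exemplum,42,54.0,49.0,0.5
tenor,Exemplum,43,52.0,49.5,0.5
tenor,Exemplum,44,52.0,50.0,1.0
tenor,Exemplum,45,51.0,51.0,1.0
tenor,Exemplum,46,50.0,52.0,0.5
tenor,Exemplum,47,50.0,52.5,2.0
tenor,Exemplum,48,50.0,54.5,1.0
tenor,Exemplum,49,50.0,55.5,1.0
tenor,Exemplum,50,50.0,56.5,1.0
tenor,Exemplum,51,52.0,57.5,1.0
tenor,Exemplum,52,54.0,58.5,1.0
tenor,Exemplum,53,52.0,59.5,1.0
tenor,Exemplum,54,53.0,60.5,0.5
tenor,Exemplum,55,51.0,61.0,1.0
tenor,Exemplum,56,52.0,62.0,1.0
tenor,Exemplum,57,53.0,63.0,2.0
tenor,Exemplum,58,53.0,65.0,0.5
tenor,Exemplum,59,57.0,65.5,1.0
bassus,Exemplum,0,56.0,0.0,1.0
bassus,Exemplum,1,54.0,1.0,1.0
bassus,Exemplum,2,56.0,2.0,2.0
bassus,Exemplum,3,58.0,4.0,1.0
bassus,Exemplum,4,57.0,5.0,2.0
bassus,Exemplum,5,59.0,7.0,1.0
bassus,Exemplum,6,61.0,8.0,1.0
bassus,Exemplum,7,62.0,9.0,1.0
bassus,Exemplum,8,62.0,10.0,0.5
bassus,Exemplum,9,62.0,10.5,1.0
bassus,Exemplum,10,62.0,11.5,1.0
bassus,Exemplum,11,62.0,12.5,1.0
bassus,Exemplum,12,61.0,13.5,2.0
bassus,Exemplum,13,61.0,15.5,0.5
bassus,Exemplum,14,62.0,16.0,1.0
bassus,Exemplum,15,62.0,17.0,0.5
bassus,Exemplum,16,62.0,17.5,1.0
bassus,Exemplum,17,62.0,18.5,2.0
bassus,Exemplum,18,62.0,20.5,2.0
bassus,Exemplum,19,62.0,22.5,1.0
bassus,Exemplum,20,62.0,23.5,1.0
bassus,Exemplum,21,60.0,24.5,1.0
bassus,Exemplum,22,62.0,25.5,2.0
bassus,Exemplum,23,62.0,27.5,1.0
bassus,Exemplum,24,62.0,28.5,2.0
bassus,Exemplum,25,58.0,30.5,2.0
bassus,Exemplum,26,56.0,32.5,1.0
bassus,Exemplum,27,56.0,33.5,2.0
bassus,Exemplum,28,54.0,35.5,0.5
bassus,Exemplum,29,56.0,36.0,1.0
bassus,Exemplum,30,57.0,37.0,1.0
bassus,Exemplum,31,56.0,38.0,0.5
bassus,Exemplum,32,57.0,38.5,0.5
bassus,Exemplum,33,58.0,39.0,0.5
bassus,Exemplum,34,60.0,39.5,1.0
bassus,Exemplum,35,58.0,40.5,2.0
bassus,Exemplum,36,59.0,42.5,0.5
bassus,Exemplum,37,57.0,43.0,2.0
bassus,Exemplum,38,58.0,45.0,1.0
bassus,Exemplum,39,60.0,46.0,1.0
bassus,Exemplum,40,59.0,47.0,1.0
bassus,Exemplum,41,59.0,48.0,0.5
bassus,Exemplum,42,58.0,48.5,1.0
bassus,Exemplum,43,60.0,49.5,0.5
bassus,Exemplum,44,61.0,50.0,1.0
bassus,Exemplum,45,61.0,51.0,2.0
bassus,Exemplum,46,62.0,53.0,1.0
bassus,Exemplum,47,62.0,54.0,0.5
bassus,Exemplum,48,62.0,54.5,0.5
bassus,Exemplum,49,61.0,55.0,1.0
bassus,Exemplum,50,62.0,56.0,0.5
bassus,Exemplum,51,61.0,56.5,1.0
bassus,Exemplum,52,62.0,57.5,1.0
bassus,Exemplum,53,60.0,58.5,2.0
bassus,Exemplum,54,59.0,60.5,1.0
bassus,Exemplum,55,62.0,61.5,1.0
bassus,Exemplum,56,61.0,62.5,2.0
bassus,Exemplum,57,62.0,64.5,1.0
bassus,Exemplum,58,62.0,65.5,1.0
bassus,Exemplum,59,62.0,66.5,1.0
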
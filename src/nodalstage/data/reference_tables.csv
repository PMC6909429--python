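stage,kind,n,m,value_percent
T1,accuracy,4,1,21.9
T1,accuracy,4,2,8.2
T1,accuracy,4,3,2.8
T1,accuracy,5,1,26.9
T1,accuracy,5,2,11.7
T1,accuracy,5,3,4.9
T1,accuracy,6,1,32.3
T1,accuracy,6,2,15.8
T1,accuracy,6,3,7.9
T1,accuracy,7,1,38.2
T1,accuracy,7,2,20.7
T1,accuracy,7,3,12.0
T1,accuracy,8,1,44.4
T1,accuracy,8,2,26.4
T1,accuracy,8,3,17.2
T1,accuracy,9,1,51.2
T1,accuracy,9,2,33.1
T1,accuracy,9,3,23.6
T1,accuracy,10,1,58.4
T1,accuracy,10,2,40.8
T1,accuracy,10,3,31.4
T1,accuracy,11,1,66.0
T1,accuracy,11,2,49.7
T1,accuracy,11,3,40.9
T1,accuracy,12,1,74.0
T1,accuracy,12,2,59.9
T1,accuracy,12,3,52.4
T1,accuracy,13,1,82.4
T1,accuracy,13,2,71.5
T1,accuracy,13,3,66.1
T1,accuracy,14,1,91.1
T1,accuracy,14,2,84.8
T1,accuracy,14,3,82.0
T2,accuracy,4,1,16.3
T2,accuracy,4,2,5.4
T2,accuracy,4,3,1.5
T2,accuracy,5,1,21.1
T2,accuracy,5,2,8.4
T2,accuracy,5,3,3.1
T2,accuracy,6,1,26.3
T2,accuracy,6,2,12.1
T2,accuracy,6,3,5.5
T2,accuracy,7,1,32.2
T2,accuracy,7,2,16.8
T2,accuracy,7,3,8.8
T2,accuracy,8,1,38.6
T2,accuracy,8,2,22.3
T2,accuracy,8,3,13.5
T2,accuracy,9,1,45.6
T2,accuracy,9,2,29.0
T2,accuracy,9,3,19.6
T2,accuracy,10,1,53.3
T2,accuracy,10,2,36.8
T2,accuracy,10,3,27.4
T2,accuracy,11,1,61.5
T2,accuracy,11,2,45.9
T2,accuracy,11,3,37.1
T2,accuracy,12,1,70.3
T2,accuracy,12,2,56.5
T2,accuracy,12,3,48.9
T2,accuracy,13,1,79.7
T2,accuracy,13,2,68.9
T2,accuracy,13,3,63.2
T2,accuracy,14,1,89.6
T2,accuracy,14,2,83.3
T2,accuracy,14,3,80.1
T3,accuracy,4,1,12.9
T3,accuracy,4,2,4.8
T3,accuracy,4,3,1.3
T3,accuracy,5,1,17.0
T3,accuracy,5,2,7.8
T3,accuracy,5,3,2.8
T3,accuracy,6,1,21.6
T3,accuracy,6,2,11.5
T3,accuracy,6,3,5.4
T3,accuracy,7,1,26.8
T3,accuracy,7,2,16.1
T3,accuracy,7,3,9.1
T3,accuracy,8,1,32.6
T3,accuracy,8,2,21.6
T3,accuracy,8,3,14.3
T3,accuracy,9,1,39.3
T3,accuracy,9,2,28.1
T3,accuracy,9,3,21.2
T3,accuracy,10,1,46.8
T3,accuracy,10,2,35.5
T3,accuracy,10,3,30.0
T3,accuracy,11,1,55.3
T3,accuracy,11,2,44.2
T3,accuracy,11,3,40.6
T3,accuracy,12,1,64.9
T3,accuracy,12,2,54.5
T3,accuracy,12,3,52.9
T3,accuracy,13,1,75.6
T3,accuracy,13,2,66.7
T3,accuracy,13,3,66.6
T3,accuracy,14,1,87.3
T3,accuracy,14,2,81.6
T3,accuracy,14,3,82.2
T1,n2_probability,4,1,33.1
T1,n2_probability,4,2,75.7
T1,n2_probability,4,3,97.2
T1,n2_probability,5,1,25.3
T1,n2_probability,5,2,67.4
T1,n2_probability,5,3,95.1
T1,n2_probability,6,1,18.6
T1,n2_probability,6,2,58.6
T1,n2_probability,6,3,92.1
T1,n2_probability,7,1,13.1
T1,n2_probability,7,2,49.5
T1,n2_probability,7,3,88.0
T1,n2_probability,8,1,8.6
T1,n2_probability,8,2,40.3
T1,n2_probability,8,3,82.8
T1,n2_probability,9,1,5.1
T1,n2_probability,9,2,31.3
T1,n2_probability,9,3,76.4
T1,n2_probability,10,1,2.7
T1,n2_probability,10,2,22.6
T1,n2_probability,10,3,68.6
T1,n2_probability,11,1,1.1
T1,n2_probability,11,2,14.6
T1,n2_probability,11,3,59.1
T1,n2_probability,12,1,0.3
T1,n2_probability,12,2,7.9
T1,n2_probability,12,3,47.6
T1,n2_probability,13,1,0.0
T1,n2_probability,13,2,2.8
T1,n2_probability,13,3,33.9
T1,n2_probability,14,1,0.0
T1,n2_probability,14,2,0.0
T1,n2_probability,14,3,18.0
T2,n2_probability,4,1,42.1
T2,n2_probability,4,2,82.6
T2,n2_probability,4,3,98.5
T2,n2_probability,5,1,32.7
T2,n2_probability,5,2,74.8
T2,n2_probability,5,3,96.9
T2,n2_probability,6,1,24.3
T2,n2_probability,6,2,65.9
T2,n2_probability,6,3,94.5
T2,n2_probability,7,1,17.2
T2,n2_probability,7,2,56.3
T2,n2_probability,7,3,91.2
T2,n2_probability,8,1,11.4
T2,n2_probability,8,2,46.3
T2,n2_probability,8,3,86.5
T2,n2_probability,9,1,6.9
T2,n2_probability,9,2,36.2
T2,n2_probability,9,3,80.4
T2,n2_probability,10,1,3.6
T2,n2_probability,10,2,26.4
T2,n2_probability,10,3,72.6
T2,n2_probability,11,1,1.5
T2,n2_probability,11,2,17.3
T2,n2_probability,11,3,62.9
T2,n2_probability,12,1,0.4
T2,n2_probability,12,2,9.4
T2,n2_probability,12,3,51.1
T2,n2_probability,13,1,0.0
T2,n2_probability,13,2,3.4
T2,n2_probability,13,3,36.8
T2,n2_probability,14,1,0.0
T2,n2_probability,14,2,0.0
T2,n2_probability,14,3,19.9
T3,n2_probability,4,1,43.3
T3,n2_probability,4,2,83.3
T3,n2_probability,4,3,98.7
T3,n2_probability,5,1,33.4
T3,n2_probability,5,2,74.7
T3,n2_probability,5,3,97.2
T3,n2_probability,6,1,24.8
T3,n2_probability,6,2,65.1
T3,n2_probability,6,3,94.6
T3,n2_probability,7,1,17.6
T3,n2_probability,7,2,54.8
T3,n2_probability,7,3,90.9
T3,n2_probability,8,1,11.8
T3,n2_probability,8,2,44.3
T3,n2_probability,8,3,85.7
T3,n2_probability,9,1,7.2
T3,n2_probability,9,2,34.1
T3,n2_probability,9,3,78.8
T3,n2_probability,10,1,3.9
T3,n2_probability,10,2,24.5
T3,n2_probability,10,3,70.0
T3,n2_probability,11,1,1.7
T3,n2_probability,11,2,16.0
T3,n2_probability,11,3,59.4
T3,n2_probability,12,1,0.5
T3,n2_probability,12,2,8.8
T3,n2_probability,12,3,47.1
T3,n2_probability,13,1,0.0
T3,n2_probability,13,2,3.3
T3,n2_probability,13,3,33.4
T3,n2_probability,14,1,0.0
T3,n2_probability,14,2,0.0
T3,n2_probability,14,3,17.8
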
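x_deg,y_deg,fibre_angle_deg
-9,21,138.814
-3,21,130.601
3,21,119.745
9,21,105.945
-15,15,153.435
-9,15,147.995
-3,15,140.194
3,15,128.66
9,15,111.801
15,15,90.0
-21,9,165.964
-15,9,163.301
-9,9,159.444
-3,9,153.435
3,9,143.13
9,9,123.69
15,9,90.0
21,9,56.31
-27,3,175.914
-21,3,175.236
-15,3,174.289
-9,3,172.875
-3,3,170.538
3,3,171.964
9,3,159.435
21,3,26.565
-27,-3,-175.914
-21,-3,-175.236
-15,-3,-174.289
-9,-3,-172.875
-3,-3,-170.538
3,-3,-171.964
9,-3,-159.435
21,-3,-26.565
-21,-9,-165.964
-15,-9,-163.301
-9,-9,-159.444
-3,-9,-153.435
3,-9,-143.13
9,-9,-123.69
15,-9,-90.0
21,-9,-56.31
-15,-15,-153.435
-9,-15,-147.995
-3,-15,-140.194
3,-15,-128.66
9,-15,-111.801
15,-15,-90.0
-9,-21,-138.814
-3,-21,-130.601
3,-21,-119.745
9,-21,-105.945
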
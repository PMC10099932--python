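(* Normative syntax reference for the extended nanomaterial line notation.
   Inputs are first ASCII-normalized: sigma -> "sd", any dash variant -> "-",
   micro sign -> "u", ellipsis -> "...", "- 35" -> "-35".  All character
   offsets reported by the parser are 0-based into the normalized string. *)

representation  = [ "NInChI=" ] , version , component , { "!" , component } ,
                  { "/" , cross_layer } ;
version         = digit , { digit } , letter ;          (* e.g. "1A" *)

component       = "/" , composition , { "/" , sublayer } ;
composition     = token ;                               (* opaque InChI formula *)
sublayer        = morphology | size | crystal | chirality | opaque_layer ;

morphology      = "m" , ( category | "[" , shape_expr , "]" ) ;
category        = "sp" | "sh" | name ;                  (* msp sphere, msh shell *)
size            = "s" , ( number | "[" , dist_expr , "]" ) ,
                  [ qualifier ] , [ exponent ] ;
qualifier       = "d" | "t" | "l" ;                     (* diameter, thickness *)
exponent        = [ "-" ] , digit , { digit } ;         (* SI power of metre *)
crystal         = "k" , ( "[" , token , "]" | token ) ; (* opaque space group *)
chirality       = "w" , token ;                         (* opaque chiral vector *)
opaque_layer    = letter , token ;                      (* preserved with warning *)

cross_layer     = overall | interface | comment | macro | opaque_layer ;
overall         = "y" , [ ordering ] , [ mixture ] ;
ordering        = index , { "&" , index } ;             (* inside-out, 1-based *)
mixture         = ( "{" , items , "}" | "..." ) , ":" , "{" , fractions , "}" ,
                  [ unit ] ;
items           = item , { "," , item } ;
item            = index | token ;
fractions       = [ fraction , { "," , fraction } ] ;
fraction        = number | dist_expr ;                  (* e.g. cdf(1,0.995) *)
interface       = "i" , index , "-" , index , "[" , relation ,
                  [ ":" , token ] , [ ";" , number ] , "]" ;
relation        = "bond" | "contains" | "coats" | "bonded" | "mixed_with" | name ;
comment         = "c{" , name , "[" , [ values ] , "]" , "}" ;
values          = value , { ";" , value } ;
value           = quoted | token ;
macro           = "d{" , ( macro_def | macro_use ) , "}" ;
macro_def       = name , [ "(" , params , ")" ] , ":" , "=" , text ;
params          = param , { "," , param } ;
param           = "%" , name ;
macro_use       = name , [ "(" , args , ")" ] ;
args            = text , { "," , text } ;

dist_expr       = dist_term , { ( "*" | "+" ) , dist_term } , [ unit ] ;
dist_term       = ( "pdf" | "cdf" | "rcdf" ) , "(" , number ,
                  { "," , dist_param } , ")" ;
dist_param      = number                                (* probability *)
                | "sd" , "=" , number
                | "m" , "=" , number
                | "ci" , "=" , "(" , name , "," , number , ")" ;
unit            = "nm" | "um" | "mm" | "m" | "mg/L" | "g/L" ;

shape_expr      = harm_term , { "+" , harm_term }
                | "bbox" , "(" , [ bbox_axes ] , ")" ;
harm_term       = "Y" , "(" , integer , "," , integer , ")" ,
                  { "*" , ( scale | number ) } ;
scale           = "scale" , "(" , number , "," , number , "," , number , ")" ;
bbox_axes       = dist_expr , { ";" , dist_expr } ;     (* up to three axes *)

index           = digit , { digit } ;
number          = [ "-" ] , digit , { digit } , [ "." , digit , { digit } ] ,
                  [ ( "e" | "E" ) , [ "-" | "+" ] , digit , { digit } ] ;
integer         = [ "-" ] , digit , { digit } ;
name            = letter , { letter | digit | "_" } ;
token           = (* any characters except the active delimiters at depth 0 *) ;
quoted          = '"' , { any_character - '"' } , '"' ;
text            = (* balanced-bracket free text *) ;
letter          = "A" | ... | "Z" | "a" | ... | "z" ;
digit           = "0" | ... | "9" ;
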